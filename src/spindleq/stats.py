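"""Condition-comparison statistics for per-cell measurements.

Two-sample Student's t-tests (unpaired by default, paired when the same
cells are compared across parameters), Spearman rank correlation with an
OLS overlay line for plotting, and per-condition summaries (mean, SD, 95%
confidence interval of the mean). Significance stars follow the usual
scheme: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001. No
multiple-testing correction is applied; see the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ConditionComparison", "two_sample_ttest", "significance_stars",
           "spearman_corr", "condition_summary"]


@dataclass
class ConditionComparison:
    """Result of one two-condition comparison."""

    metric: str
    t_statistic: float
    p_value: float
    stars: str
    paired: bool
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    flagged: bool = False   # degenerate input (zero variance) handled by
                            # convention


def significance_stars(p: float) -> str:
    """Star annotation for a p-value (empty string when p >= 0.05)."""
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                          (5e-2, "*")):
        if p < thresh:
            return stars
    return ""


def two_sample_ttest(a, b, paired: bool = False,
                     metric: str = "") -> ConditionComparison:
    """Classical two-sample Student's t-test, two-sided.

    Unpaired uses the equal-variance pooled statistic; paired requires
    equal sample sizes. Zero variance in both groups with equal means is
    reported as t=0, p=1 by convention and flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if paired and a.size != b.size:
        raise ValueError("paired test requires equal group sizes")
    flagged = False
    if paired:
        d = a - b
        if d.std(ddof=1) == 0:
            t_stat, p = (0.0, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
            flagged = True
        else:
            t_stat, p = sps.ttest_rel(a, b)
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if np.isclose(a.mean(), b.mean()):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = np.inf, 0.0
            flagged = True
        else:
            t_stat, p = sps.ttest_ind(a, b, equal_var=True)
    return ConditionComparison(metric=metric, t_statistic=float(t_stat),
                               p_value=float(p),
                               stars=significance_stars(float(p)),
                               paired=paired, n_a=a.size, n_b=b.size,
                               mean_a=float(a.mean()), mean_b=float(b.mean()),
                               flagged=flagged)


def spearman_corr(x, y):
    """Spearman rank correlation rs, plus the OLS line of the raw values.

    rs is the Pearson correlation of midranks (ties get the mean of the
    ranks they span). Returns ``(rs, p_value, (slope, intercept))`` where
    the OLS line is fit to the raw values for the plotting overlay.
    Constant input makes rs undefined (nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rs undefined", stacklevel=2)
        return np.nan, np.nan, (np.nan, np.nan)
    rs, p = sps.spearmanr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return float(rs), float(p), (float(slope), float(intercept))


def condition_summary(table: pd.DataFrame, value_col: str = "value",
                      group_cols=("condition", "metric"),
                      exemplar_col: str | None = None) -> pd.DataFrame:
    """Per-condition mean, SD, 95% CI of the mean and n.

    The CI uses the t-quantile with n-1 degrees of freedom. A group with a
    single observation gets its value as the mean and NaN SD/CI, flagged in
    the ``flagged`` column. When ``exemplar_col`` names a boolean column,
    the exemplar cells' values are echoed per group.
    """
    group_cols = list(group_cols)
    rows = []
    for keys, sub in table.groupby(group_cols, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = sub[value_col].to_numpy(dtype=float)
        n = vals.size
        mean = float(vals.mean())
        if n > 1:
            sd = float(vals.std(ddof=1))
            half = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
            ci_lo, ci_hi = mean - half, mean + half
            flagged = False
        else:
            sd = ci_lo = ci_hi = np.nan
            flagged = True
        row = dict(zip(group_cols, keys))
        row.update(n=n, mean=mean, sd=sd, ci95_lo=ci_lo, ci95_hi=ci_hi,
                   flagged=flagged)
        if exemplar_col is not None and exemplar_col in sub.columns:
            ex = sub.loc[sub[exemplar_col].astype(bool), value_col]
            row["exemplar_values"] = ";".join(f"{v:g}" for v in ex)
        rows.append(row)
    return pd.DataFrame(rows)
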
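"""Velocity and elongation metrics from distance-versus-time series.

All estimators operate on a :class:`DistanceSeries` whose time axis is
relative to anaphase onset (so every estimate is invariant to shifting the
whole movie in time). Velocities are reported in μm/min; distances in μm.

Two published procedures coexist and both are provided: an ordinary
least-squares slope over a configurable window (default 60-180 s after
onset, the 1-3 min interval; the 60-120 s regression window is available
via config), and the two-point estimate (d(3 min) - d(1 min)) / (2 min).
On noise-free linear data the two agree to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceSeries", "VelocityEstimate", "windowed_velocity_ols",
    "two_point_velocity", "poleward_velocity", "net_elongation",
    "segregation_velocity_windowed", "distance_series",
]


@dataclass
class DistanceSeries:
    """Distance between one object pair versus time from anaphase onset.

    ``t`` is seconds relative to onset (strictly increasing); ``d`` is μm.
    ``delta`` (Δd, the distance minus its value at the last pre-onset
    frame) is available once an onset is known.
    """

    t: np.ndarray
    d: np.ndarray
    pair: str = ""
    d_pre_onset: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.t.shape != self.d.shape:
            raise ValueError("t and d must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def delta(self) -> np.ndarray:
        """Δd: distance minus the last pre-onset distance."""
        if self.d_pre_onset is None:
            raise ValueError("Δd undefined: onset reference not set")
        return self.d - self.d_pre_onset

    def value_at(self, t_query: float) -> float:
        """Distance at ``t_query`` s, linearly interpolated between frames."""
        if t_query < self.t[0] or t_query > self.t[-1]:
            raise ValueError(
                f"t={t_query}s outside covered range "
                f"[{self.t[0]}, {self.t[-1]}]s")
        return float(np.interp(t_query, self.t, self.d))


@dataclass
class VelocityEstimate:
    """A velocity with its estimation window and uncertainty."""

    value: float            # μm/min
    window: tuple           # (t1, t2) s relative to onset
    method: str             # "ols" | "two_point"
    n_points: int
    stderr: float           # μm/min, slope standard error (nan for 2-point)


def distance_series(track_a, track_b, onset_time: float = 0.0,
                    pair: str = "") -> DistanceSeries:
    """Pairwise distance series from two track DataFrames.

    Each input needs columns ``t_s``, ``x_um``, ``y_um``; frames present in
    both tracks are used and time is re-referenced to ``onset_time``.
    """
    a = track_a.set_index("frame")
    b = track_b.set_index("frame")
    common = a.index.intersection(b.index).sort_values()
    dx = a.loc[common, "x_um"].to_numpy() - b.loc[common, "x_um"].to_numpy()
    dy = a.loc[common, "y_um"].to_numpy() - b.loc[common, "y_um"].to_numpy()
    t = a.loc[common, "t_s"].to_numpy() - onset_time
    d = np.hypot(dx, dy)
    pre = d[t <= 0]
    return DistanceSeries(t, d, pair=pair,
                          d_pre_onset=float(pre[-1]) if pre.size else None)


def _ols_slope(t, d):
    """Slope, intercept and slope SE of d on t (t in s, slope in μm/s)."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    n = t.size
    tbar = t.mean()
    sxx = np.sum((t - tbar) ** 2)
    if sxx == 0:
        raise ValueError("degenerate window: no time spread")
    slope = np.sum((t - tbar) * (d - d.mean())) / sxx
    resid = d - (d.mean() + slope * (t - tbar))
    if n > 2:
        se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx)
    else:
        se = np.nan
    return slope, se


def windowed_velocity_ols(series: DistanceSeries,
                          window=(60.0, 180.0)) -> VelocityEstimate:
    """OLS slope of d versus t over a closed window, in μm/min.

    Requires at least 3 samples inside the window and a window that starts
    at or after onset (t >= 0).
    """
    t1, t2 = window
    if t1 >= t2:
        raise ValueError("window must satisfy t1 < t2")
    if t2 < 0:
        raise ValueError("window precedes anaphase onset")
    mask = (series.t >= t1) & (series.t <= t2)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} samples inside window [{t1}, {t2}]s; "
            "need >= 3")
    slope, se = _ols_slope(series.t[mask], series.d[mask])
    return VelocityEstimate(value=slope * 60.0, window=(t1, t2),
                            method="ols", n_points=int(mask.sum()),
                            stderr=se * 60.0)


def two_point_velocity(series: DistanceSeries, t1: float = 60.0,
                       t2: float = 180.0) -> VelocityEstimate:
    """Two-point velocity (d(t2) - d(t1)) / (t2 - t1) in μm/min.

    Endpoints are linearly interpolated between bracketing frames when no
    exact sample exists; the default window is 1-3 min after onset.
    """
    if t1 >= t2:
        raise ValueError("need t1 < t2")
    d1 = series.value_at(t1)
    d2 = series.value_at(t2)
    v = (d2 - d1) / (t2 - t1) * 60.0
    return VelocityEstimate(value=v, window=(t1, t2), method="two_point",
                            n_points=2, stderr=np.nan)


def poleward_velocity(kt_track, pole_tracks, window=(60.0, 180.0),
                      onset_time: float = 0.0) -> VelocityEstimate:
    """Anaphase A: approach speed of a kinetochore toward its pole.

    The kinetochore is assigned to the nearer pole at onset (an ambiguous,
    equidistant assignment is an error listing the candidates); the OLS
    slope of the kinetochore-to-pole distance is negated so that poleward
    motion is reported as a positive approach speed.
    """
    onset_frame_candidates = kt_track.loc[
        kt_track["t_s"] >= onset_time, "frame"]
    if onset_frame_candidates.empty:
        raise ValueError("kinetochore track does not cover anaphase onset")
    f0 = int(onset_frame_candidates.iloc[0])
    kt0 = kt_track.set_index("frame").loc[f0]
    dists = []
    for p in pole_tracks:
        p0 = p.set_index("frame").loc[f0]
        dists.append(np.hypot(kt0["x_um"] - p0["x_um"],
                              kt0["y_um"] - p0["y_um"]))
    if len(pole_tracks) != 2:
        raise ValueError("need exactly two pole tracks")
    if np.isclose(dists[0], dists[1]):
        raise ValueError(
            "ambiguous pole assignment: kinetochore equidistant from poles "
            f"(candidates at {dists[0]:.3f} and {dists[1]:.3f} μm)")
    pole = pole_tracks[int(np.argmin(dists))]
    series = distance_series(kt_track, pole, onset_time=onset_time,
                             pair="kt-pole")
    est = windowed_velocity_ols(series, window)
    return VelocityEstimate(value=-est.value, window=est.window,
                            method=est.method, n_points=est.n_points,
                            stderr=est.stderr)


def net_elongation(pole_series: DistanceSeries,
                   horizon: float = 300.0) -> float:
    """Net spindle elongation d(onset + horizon) - d(onset), μm.

    Endpoints are interpolated as in :func:`two_point_velocity`; the data
    must cover both onset and the horizon.
    """
    return pole_series.value_at(horizon) - pole_series.value_at(0.0)


def segregation_velocity_windowed(sister_series: DistanceSeries,
                                  mode: str = "standard",
                                  t_pa: float | None = None,
                                  pa_window_length: float = 60.0
                                  ) -> VelocityEstimate:
    """Chromosome segregation velocity over the mode's published window.

    ``standard``: OLS over 60-180 s after onset; ``crispr``: the first
    minute of anaphase (0-60 s); ``pa``: from the photoactivation time
    ``t_pa`` (s after onset) to ``t_pa + pa_window_length``.
    """
    if mode == "standard":
        window = (60.0, 180.0)
    elif mode == "crispr":
        window = (0.0, 60.0)
    elif mode == "pa":
        if t_pa is None:
            raise ValueError("mode='pa' requires t_pa")
        window = (t_pa, t_pa + pa_window_length)
    else:
        raise ValueError(f"unknown mode {mode!r}; use pa | crispr | standard")
    return windowed_velocity_ols(sister_series, window)
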
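"""Parameter-recovery benchmark suites.

Every quantification stage of the package is scored against the synthetic
generator's ground truth: velocities against the kinematic inputs, the
stability ratio against the generator's survival fraction, sliding slopes
against the programmed sliding velocity, comet detection against the true
comet positions, and the statistics layer against brute-force oracles.
All randomness derives from a single master seed via ``SeedSequence``
spawning, so every suite is reproducible bit for bit.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy import stats as sps

from . import stats as sqstats
from .cohort import CohortCondition, run_cohort
from .comets import (calibrate_quality_threshold, detect_comets_stack,
                     make_anaphase_geometry, trace_kymograph)
from .kinematics import DistanceSeries, two_point_velocity, \
    windowed_velocity_ols
from .photoactivation import build_kymograph, default_axis_line, pa_assay, \
    stability_ratio
from .simulate import (CometSimParams, PABandSimParams, RenderOptics,
                       SpindleSimParams, flux_for_snr, simulate_comets,
                       simulate_pa_band, simulate_spindle_tracks)
from .tracking import NO_ONSET, detect_anaphase_onset

__all__ = [
    "child_seeds", "velocity_recovery_suite", "onset_detection_suite",
    "stability_suite", "sliding_suite", "comet_suite", "stats_oracle_suite",
    "end_to_end_suite",
]

PX = 0.083


def child_seeds(master: int, label: str, n: int):
    """n reproducible sub-seeds (< 2**31) for one suite."""
    from zlib import crc32

    ss = np.random.SeedSequence((int(master), crc32(label.encode())))
    rng = np.random.default_rng(ss)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def velocity_recovery_suite(master: int = 0,
                            v_values=(0.0, 0.5, 1.0, 2.0, 3.0),
                            n_seeds: int = 50) -> dict:
    """Elongation-velocity recovery on jittered tracks (15 s sampling,
    0.05 μm jitter) against the analytic OLS slope-error prediction."""
    window = (60.0, 180.0)
    out = {}
    for v in v_values:
        est = []
        analytic_se = None
        for seed in child_seeds(master, f"velocity_{v}", n_seeds):
            p = SpindleSimParams(v_B=v, jitter_sd=0.05, n_frames=24,
                                 n_kt_pairs=0, seed=seed)
            truth = simulate_spindle_tracks(p)
            tr = truth.tracks
            d = (tr[tr["object_id"] == "pole_2"]["x_um"].to_numpy()
                 - tr[tr["object_id"] == "pole_1"]["x_um"].to_numpy())
            t = truth.info["t_s"] - p.onset_time
            series = DistanceSeries(t, np.abs(d))
            est.append(windowed_velocity_ols(series, window).value)
            if analytic_se is None:
                tw = t[(t >= window[0]) & (t <= window[1])]
                sxx = ((tw - tw.mean()) ** 2).sum()
                analytic_se = np.sqrt(2.0) * 0.05 / np.sqrt(sxx) * 60.0
        est = np.asarray(est)
        out[v] = {
            "mean": float(est.mean()),
            "bias": float(est.mean() - v),
            "bias_pct": float((est.mean() - v) / v * 100.0) if v > 0
            else np.nan,
            "sd": float(est.std(ddof=1)),
            "analytic_sd": float(analytic_se),
            "sd_ratio": float(est.std(ddof=1) / analytic_se),
            "n": n_seeds,
        }
    # noiseless equivalence of the two published estimators
    t = np.arange(0, 300, 15.0)
    s = DistanceSeries(t, 10.0 + 1.77 / 60.0 * t)
    out["two_point_vs_ols_diff"] = abs(
        two_point_velocity(s, 60, 180).value
        - windowed_velocity_ols(s, (60, 180)).value)
    return out


def onset_detection_suite(master: int = 0, n_seeds: int = 100,
                          true_onset: int = 20,
                          noise_floor: float = 0.3) -> dict:
    """Onset recovery on jittered pole-distance series
    (jitter = noise_floor / 3)."""
    hits = 0
    for seed in child_seeds(master, "onset", n_seeds):
        rng = np.random.default_rng(seed)
        t = np.arange(40) * 15.0
        d = 12.0 + np.maximum(t - true_onset * 15.0, 0.0) * 2.0 / 60.0
        d = d + rng.normal(0.0, noise_floor / 3.0, d.size)
        onset = detect_anaphase_onset(d, noise_floor=noise_floor)
        if onset != NO_ONSET and abs(onset - true_onset) <= 1:
            hits += 1
    return {"hit_rate": hits / n_seeds, "hits": hits, "n": n_seeds}


def _pa_optics(seed, snr=10.0, background=20.0):
    optics = RenderOptics(background=background, seed=seed)
    optics.flux = flux_for_snr(snr, optics, PX)
    return optics


def stability_suite(master: int = 0, survivals=(0.5, 0.7, 0.9),
                    n_seeds: int = 20, snr: float = 10.0) -> dict:
    """Survival-fraction recovery from bleach-corrected PA movies."""
    out = {}
    for surv in survivals:
        vals = []
        for seed in child_seeds(master, f"stability_{surv}", n_seeds):
            pa = PABandSimParams(v_slide=1.5, survival_30s=surv,
                                 bleach_rate=0.004, n_frames=45, seed=seed,
                                 background_level=20.0)
            stack, _ = simulate_pa_band(pa, optics=_pa_optics(seed, snr))
            corrected, _, _ = stability_ratio(
                stack, default_axis_line(stack), thickness_px=56)
            vals.append(corrected)
        vals = np.asarray(vals)
        out[surv] = {"mean": float(vals.mean()),
                     "error": float(vals.mean() - surv),
                     "sd": float(vals.std(ddof=1)), "n": n_seeds}
    return out


def sliding_suite(master: int = 0, v_values=(0.0, 0.5, 1.0, 2.0),
                  n_seeds: int = 20, snr: float = 10.0) -> dict:
    """Sliding-velocity recovery from PA movies (zero-sliding control
    included)."""
    out = {}
    for v in v_values:
        vals = []
        for seed in child_seeds(master, f"sliding_{v}", n_seeds):
            pa = PABandSimParams(v_slide=v, survival_30s=0.8,
                                 bleach_rate=0.0, n_frames=45, seed=seed,
                                 background_level=20.0)
            stack, _ = simulate_pa_band(pa, optics=_pa_optics(seed, snr))
            res = pa_assay(stack, profile_thickness_px=56)
            vals.append(res.sliding_velocity.value)
        vals = np.asarray(vals)
        out[v] = {"mean": float(vals.mean()),
                  "error_pct": float((vals.mean() - v) / v * 100.0)
                  if v > 0 else np.nan,
                  "sd": float(vals.std(ddof=1)), "n": n_seeds}
    return out


def _match_detections(det, truth, radius=0.5):
    tp = fp = fn = 0
    frames = sorted(set(truth["frame"]).union(det["frame"]))
    for f in frames:
        d = det[det["frame"] == f]
        g = truth[truth["frame"] == f]
        if len(g) == 0:
            fp += len(d)
            continue
        if len(d) == 0:
            fn += len(g)
            continue
        from scipy.spatial import cKDTree

        tree = cKDTree(np.column_stack([g["x_um"], g["y_um"]]))
        dist, idx = tree.query(np.column_stack([d["x_um"], d["y_um"]]))
        used = set()
        m = 0
        for dd, ii in sorted(zip(dist, idx)):
            if dd <= radius and ii not in used:
                used.add(ii)
                m += 1
        tp += m
        fp += len(d) - m
        fn += len(g) - m
    return tp, fp, fn


def comet_suite(master: int = 0, snr: float = 8.0) -> dict:
    """Comet detection, region assignment, Poisson consistency, kymograph
    velocity and the out-of-cell calibration rule."""
    geo = make_anaphase_geometry()
    seeds = child_seeds(master, "comets", 4)

    # detection precision / recall at SNR 8 over 3 movies
    tp = fp = fn = 0
    last_stack = None
    for seed in seeds[:3]:
        cp = CometSimParams(n_frames=30, seed=seed)
        optics = RenderOptics(psf_sigma=0.3, seed=seed)
        optics.flux = flux_for_snr(snr, optics, PX)
        stack, truth = simulate_comets(cp, geo, optics)
        det = detect_comets_stack(stack)
        a, b, c = _match_detections(det, truth.tracks)
        tp, fp, fn = tp + a, fp + b, fn + c
        last_stack = stack
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)

    # out-of-cell fraction at the auto-calibrated threshold
    thr = calibrate_quality_threshold(last_stack, geo)
    det = detect_comets_stack(last_stack, quality_threshold=thr)
    outside = float(np.mean(~geo.contains(det["x_um"].to_numpy(),
                                          det["y_um"].to_numpy())))

    # region assignment vs ray-casting oracle
    rng = np.random.default_rng(child_seeds(master, "regions", 1)[0])
    x = rng.uniform(-18, 18, 500)
    y = rng.uniform(-13, 13, 500)
    labels = geo.assign(x, y)
    mismatches = 0
    polys = (("midzone", geo.midzone), ("astral1", geo.astral1),
             ("astral2", geo.astral2))
    for xi, yi, lab in zip(x, y, labels):
        expected = "other"
        for name, poly in polys:
            if _ray_cast(xi, yi, list(poly.exterior.coords)[:-1]):
                expected = name
                break
        if lab != expected:
            mismatches += 1

    # standing nucleation ratio vs Poisson oracle (rates 2:1)
    cp = CometSimParams(nucleation_rate_astral=1.0,
                        nucleation_rate_midzone=0.5, n_frames=100,
                        seed=seeds[3])
    _, truth = simulate_comets(cp, geo, RenderOptics(noise=False))
    n_a = truth.info["n_nucleated"]["astral"]
    n_m = truth.info["n_nucleated"]["midzone"]
    ratio = n_a / n_m
    ratio_sd = 2.0 * np.sqrt(1.0 / 100.0 + 1.0 / 50.0)

    # kymograph-derived comet velocity at 20 μm/min
    vels = []
    for seed in child_seeds(master, "comet_kymo", 6):
        cp = CometSimParams(n_frames=40, nucleation_rate_astral=0.0,
                            nucleation_rate_midzone=0.15,
                            mean_lifetime=12.0, seed=seed)
        optics = RenderOptics(psf_sigma=0.3, seed=seed)
        optics.flux = flux_for_snr(10.0, optics, PX)
        stack, _ = simulate_comets(cp, geo, optics)
        kym = build_kymograph(stack, ((-8.0, 0.0), (8.0, 0.0)),
                              thickness_px=40)
        vels += [s.velocity for s in trace_kymograph(kym)]

    return {
        "precision": precision, "recall": recall,
        "outside_fraction": outside, "calibrated_threshold": thr,
        "region_oracle_mismatches": mismatches, "n_region_points": 500,
        "nucleation_ratio": float(ratio), "ratio_z": float(
            (ratio - 2.0) / ratio_sd),
        "kymo_velocity_mean": float(np.mean(vels)), "n_traces": len(vels),
    }


def _ray_cast(x, y, vertices):
    inside = False
    j = len(vertices) - 1
    for i in range(len(vertices)):
        xi, yi = vertices[i]
        xj, yj = vertices[j]
        if (yi > y) != (yj > y):
            if x < xi + (y - yi) / (yj - yi) * (xj - xi):
                inside = not inside
        j = i
    return inside


def stats_oracle_suite(master: int = 0) -> dict:
    """Statistics layer versus brute-force oracles."""
    from itertools import product

    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(v.size)
        order = np.argsort(v, kind="stable")
        sv = v[order]
        i = 0
        while i < v.size:
            j = i
            while j < v.size and sv[j] == sv[i]:
                j += 1
            out[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return out

    # Spearman vs brute-force midranks on all tied length-6 vectors
    y = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 2.0])
    ry = midranks(y)
    max_diff_rs = 0.0
    for x in product([1.0, 2.0, 3.0], repeat=6):
        if len(set(x)) == 1:
            continue
        rs, _, _ = sqstats.spearman_corr(np.array(x), y)
        brute = float(np.corrcoef(midranks(x), ry)[0, 1])
        max_diff_rs = max(max_diff_rs, abs(rs - brute))

    # t-test p vs numerical CDF integration
    rng = np.random.default_rng(child_seeds(master, "ttest", 1)[0])
    max_diff_p = 0.0
    for _ in range(200):
        n1, n2 = rng.integers(3, 12, 2)
        a = rng.normal(0, 1, n1)
        b = rng.normal(rng.uniform(-1, 1), 1, n2)
        res = sqstats.two_sample_ttest(a, b)
        df = n1 + n2 - 2
        tail, _ = integrate.quad(lambda u: sps.t.pdf(u, df),
                                 abs(res.t_statistic), np.inf)
        max_diff_p = max(max_diff_p, abs(res.p_value - 2 * tail))

    # null p-values uniform on [0, 1]
    rng = np.random.default_rng(child_seeds(master, "nulls", 1)[0])
    pvals = np.empty(2000)
    for k in range(2000):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        pvals[k] = sqstats.two_sample_ttest(a, b).p_value
    ks_p = float(sps.kstest(pvals, "uniform").pvalue)

    return {"spearman_max_diff": max_diff_rs, "ttest_max_diff": max_diff_p,
            "ks_uniformity_p": ks_p, "n_null": 2000}


def end_to_end_suite(master: int = 0, n_cells_per_condition: int = 10,
                     check_determinism: bool = True) -> dict:
    """Two-condition cohort (control vs double motor perturbation)."""
    conditions = [
        CohortCondition("control", v_B=2.36, n_cells=n_cells_per_condition),
        CohortCondition("double_perturbation", v_B=0.35, v_A=0.3,
                        survival_30s=0.6, n_cells=n_cells_per_condition),
    ]
    out = run_cohort(conditions, seed=master)
    result = {
        "rs_sliding_segregation": out["rs_sliding_segregation"],
        "rs_sliding_elongation": out["rs_sliding_elongation"],
        "n_cells": len(out["cells"]),
        "mean_elongation_control": float(
            out["cells"].query("condition == 'control'")
            ["elongation_velocity"].mean()),
        "mean_elongation_perturbed": float(
            out["cells"].query("condition == 'double_perturbation'")
            ["elongation_velocity"].mean()),
        "cells": out["cells"],
    }
    if check_determinism:
        out2 = run_cohort(conditions, seed=master)
        result["bit_identical_rerun"] = bool(
            out["cells"].equals(out2["cells"]))
    return result
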
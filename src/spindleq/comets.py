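"""EB3 plus-end comet detection and per-region statistics.

Comets are detected per frame with a scale-matched Laplacian-of-Gaussian
(LoG) filter tuned to a 1 μm blob diameter, thresholded on a unitless
quality score and refined to sub-pixel positions by quadratic
interpolation. Detections are then attributed to the astral / midzone /
cortex partition of the cell (see :mod:`spindleq.regions`) and summarized
as per-frame counts, midzone densities per μm, astral:midzone ratios and
cortex contacts. Comet velocities and track lengths are read off
whole-spindle kymographs, where each comet trace is the hypotenuse of a
right triangle in (position, time).

Quality score: the scale-normalized LoG response divided by twice the
robust per-pixel noise sd of the frame. This calibration makes the default
threshold of 0.8 reject blank noise while keeping comets of peak SNR >= 8,
and it can be auto-raised until no more than 5% of detections fall outside
the cell boundary — the same acceptance rule the emulated analysis used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_laplace, maximum_filter
from skimage.transform import probabilistic_hough_line

from .core import ImageStack
from .photoactivation import Kymograph
from .regions import RegionPartition, make_anaphase_geometry, partition_regions

__all__ = [
    "CometTrackStats", "detect_comets_log", "detect_comets_stack",
    "comet_region_counts", "comet_kinematics_from_kymograph",
    "trace_kymograph", "calibrate_quality_threshold",
    "chromosome_mask_from_h2b", "RegionPartition", "partition_regions",
    "make_anaphase_geometry",
]


@dataclass
class CometTrackStats:
    """Velocity and length of one comet trace."""

    velocity: float      # μm/min
    track_length: float  # μm
    region: str = ""
    source: str = "kymograph"


def _robust_noise_sd(frame: np.ndarray) -> float:
    """Per-pixel noise sd from the median absolute deviation."""
    med = np.median(frame)
    mad = np.median(np.abs(frame - med))
    return float(1.4826 * mad) or 1.0


def detect_comets_log(frame: np.ndarray, pixel_size: float,
                      blob_diameter: float = 1.0,
                      quality_threshold: float = 0.8) -> pd.DataFrame:
    """LoG comet detection in one frame.

    Returns a DataFrame with columns ``x_px, y_px, quality`` (sub-pixel,
    quadratically refined). The filter scale is ``diameter / (2 sqrt(2))``
    converted to pixels.
    """
    frame = np.asarray(frame, dtype=float)
    sigma_px = blob_diameter / (2.0 * np.sqrt(2.0)) / pixel_size
    # scale-normalized negative LoG: positive response at bright blobs
    response = -(sigma_px**2) * gaussian_laplace(frame, sigma_px)
    quality_map = response / (2.0 * _robust_noise_sd(frame))
    size = max(3, int(round(sigma_px)) | 1)
    local_max = (quality_map == maximum_filter(quality_map, size=size))
    rows, cols = np.nonzero(local_max & (quality_map > quality_threshold))
    ny, nx = frame.shape
    out = []
    for r, c in zip(rows, cols):
        dx = dy = 0.0
        if 0 < c < nx - 1:
            denom = (quality_map[r, c - 1] - 2 * quality_map[r, c]
                     + quality_map[r, c + 1])
            if denom < 0:
                dx = 0.5 * (quality_map[r, c - 1]
                            - quality_map[r, c + 1]) / denom
        if 0 < r < ny - 1:
            denom = (quality_map[r - 1, c] - 2 * quality_map[r, c]
                     + quality_map[r + 1, c])
            if denom < 0:
                dy = 0.5 * (quality_map[r - 1, c]
                            - quality_map[r + 1, c]) / denom
        out.append((c + np.clip(dx, -0.5, 0.5), r + np.clip(dy, -0.5, 0.5),
                    quality_map[r, c]))
    return pd.DataFrame(out, columns=["x_px", "y_px", "quality"])


def detect_comets_stack(stack: ImageStack, blob_diameter: float = 1.0,
                        quality_threshold: float = 0.8) -> pd.DataFrame:
    """Detections for every frame, with positions in both px and μm."""
    frames = []
    for f in range(stack.n_frames):
        det = detect_comets_log(stack.data[f], stack.meta.pixel_size,
                                blob_diameter, quality_threshold)
        det.insert(0, "frame", f)
        frames.append(det)
    nonempty = [f for f in frames if len(f)]
    det = (pd.concat(nonempty, ignore_index=True) if nonempty
           else frames[0])
    if len(det):
        x_um, y_um = stack.px_to_um(det["x_px"].to_numpy(),
                                    det["y_px"].to_numpy())
        det["x_um"], det["y_um"] = x_um, y_um
    else:
        det["x_um"] = det["y_um"] = np.nan
    return det


def calibrate_quality_threshold(stack: ImageStack,
                                partition: RegionPartition,
                                blob_diameter: float = 1.0,
                                start: float = 0.8,
                                max_outside_fraction: float = 0.05,
                                step: float = 1.25,
                                max_iter: int = 30) -> float:
    """Raise the quality threshold until <= 5% of detections fall outside
    the cell boundary (the published detector calibration rule)."""
    thr = start
    for _ in range(max_iter):
        det = detect_comets_stack(stack, blob_diameter, thr)
        if len(det) == 0:
            return thr
        outside = ~partition.contains(det["x_um"].to_numpy(),
                                      det["y_um"].to_numpy())
        if outside.mean() <= max_outside_fraction:
            return thr
        thr *= step
    return thr


def comet_region_counts(detections: pd.DataFrame,
                        partition: RegionPartition) -> dict:
    """Per-frame counts per region plus the derived midzone statistics.

    Returns a dict with a per-frame DataFrame (``counts``: astral1,
    astral2, midzone, other, cortex_contacts, midzone_per_um,
    astral_midzone_ratio — the ratio is NaN on frames with an empty
    midzone) and movie-level means. Count conservation holds per frame:
    astral1 + astral2 + midzone + other = total detections.
    """
    mz_len = partition.midzone_length()
    frames = (sorted(detections["frame"].unique())
              if len(detections) else [])
    rows = []
    for f in frames:
        sub = detections[detections["frame"] == f]
        x = sub["x_um"].to_numpy()
        y = sub["y_um"].to_numpy()
        labels = partition.assign(x, y)
        n = {r: int((labels == r).sum())
             for r in ("astral1", "astral2", "midzone", "other")}
        astral = n["astral1"] + n["astral2"]
        rows.append({
            "frame": f, **n,
            "total": len(sub),
            "cortex_contacts": int(partition.in_cortex(x, y).sum()),
            "midzone_per_um": (n["midzone"] / mz_len if mz_len > 0
                               else np.nan),
            "astral_midzone_ratio": (astral / n["midzone"]
                                     if n["midzone"] > 0 else np.nan),
        })
    counts = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["frame", "astral1", "astral2", "midzone", "other", "total",
                 "cortex_contacts", "midzone_per_um", "astral_midzone_ratio"])
    with np.errstate(invalid="ignore"):
        summary = {
            "mean_astral": float(
                (counts["astral1"] + counts["astral2"]).mean())
            if len(counts) else 0.0,
            "mean_midzone": float(counts["midzone"].mean())
            if len(counts) else 0.0,
            "mean_midzone_per_um": float(
                np.nanmean(counts["midzone_per_um"]))
            if len(counts) and counts["midzone_per_um"].notna().any()
            else np.nan,
            "mean_ratio": float(np.nanmean(counts["astral_midzone_ratio"]))
            if len(counts) and counts["astral_midzone_ratio"].notna().any()
            else np.nan,
            "midzone_length_um": mz_len,
        }
    return {"counts": counts, **summary}


def comet_kinematics_from_kymograph(kymo: Kymograph,
                                    endpoints) -> CometTrackStats:
    """Comet velocity/length from one kymograph trace.

    ``endpoints`` is ``((s0_um, t0_s), (s1_um, t1_s))`` in kymograph
    coordinates; the trace is the hypotenuse of the right triangle with
    legs |Δposition| and Δtime. Velocity is |Δposition| / Δtime in μm/min.
    """
    (s0, t0), (s1, t1) = endpoints
    if t1 == t0:
        raise ValueError("zero time extent: cannot compute a velocity")
    length = abs(s1 - s0)
    velocity = length / abs(t1 - t0) * 60.0
    return CometTrackStats(velocity=velocity, track_length=length)


def trace_kymograph(kymo: Kymograph, threshold: float | None = None,
                    min_length_px: int = 12, line_gap: int = 1,
                    max_ridge_rms_px: float = 1.0,
                    min_frames: int = 8) -> list:
    """Auto-trace comet lines on a kymograph (Hough-style line detection).

    Returns a list of :class:`CometTrackStats`, one per detected trace.
    """
    img = kymo.data
    if threshold is None:
        med = np.median(img)
        mad = np.median(np.abs(img - med)) * 1.4826
        threshold = med + 4.0 * (mad if mad > 0 else img.std())
    binary = img > threshold
    baseline = np.median(img)
    noise_sd = np.median(np.abs(img - baseline)) * 1.4826
    lines = probabilistic_hough_line(binary.T, threshold=5,
                                     line_length=min_length_px,
                                     line_gap=line_gap, rng=0)
    candidates = []
    for (t0_px, s0_px), (t1_px, s1_px) in lines:
        if t1_px < t0_px:
            t0_px, s0_px, t1_px, s1_px = t1_px, s1_px, t0_px, s0_px
        if t1_px == t0_px:
            continue
        # refine against the intensity ridge: Hough endpoints on the
        # binarized streak cut across its thickness and bias the slope
        slope0 = (s1_px - s0_px) / (t1_px - t0_px)
        half = 5
        ts, cs = [], []
        for t in range(t0_px, t1_px + 1):
            if not (0 <= t < img.shape[0]):
                continue
            s_pred = s0_px + slope0 * (t - t0_px)
            lo = max(0, int(round(s_pred)) - half)
            hi = min(img.shape[1], int(round(s_pred)) + half + 1)
            seg = img[t, lo:hi] - baseline
            # only frames where the streak clearly stands above the
            # noise contribute; appearance/disappearance frames would
            # pull the centroid toward noise
            if seg.max(initial=0.0) <= 4.0 * noise_sd:
                continue
            w = np.clip(seg, 0.0, None)
            cs.append(float((w * np.arange(lo, hi)).sum() / w.sum()))
            ts.append(t)
        if len(ts) < 3:
            continue
        ts = np.asarray(ts)
        cs = np.asarray(cs)
        slope, intercept = np.polyfit(ts, cs, 1)  # px per frame
        resid = cs - (slope * ts + intercept)
        # a genuine streak follows its ridge tightly; lines stitched
        # across crossing comets zigzag between branches
        if np.sqrt(np.mean(resid**2)) > max_ridge_rms_px:
            continue
        candidates.append((ts, slope, intercept))

    # deduplicate: several Hough fragments can cover one streak; keep the
    # longest trace of each streak, as a manual tracer would
    candidates.sort(key=lambda c: -c[0].size)
    stats = []
    kept = []
    for ts, slope, intercept in candidates:
        duplicate = False
        for ts_k, slope_k, intercept_k in kept:
            t_common = np.intersect1d(ts, ts_k)
            if t_common.size == 0:
                continue
            d = np.abs((slope * t_common + intercept)
                       - (slope_k * t_common + intercept_k))
            if np.mean(d < 3.0) > 0.5:
                duplicate = True
                break
        if duplicate:
            continue
        if ts.size < min_frames:
            continue  # too brief to be a discernible comet trace
        kept.append((ts, slope, intercept))
        span = ts[-1] - ts[0]
        ds = abs(slope) * span * kymo.pixel_size
        dt = span * kymo.frame_interval
        if dt > 0:
            stats.append(CometTrackStats(velocity=ds / dt * 60.0,
                                         track_length=ds))
    return stats


def chromosome_mask_from_h2b(frame: np.ndarray) -> np.ndarray:
    """Binary chromosome mask: Otsu threshold, two largest components."""
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    frame = np.asarray(frame, dtype=float)
    mask = frame > threshold_otsu(frame)
    lab = label(mask)
    props = sorted(regionprops(lab), key=lambda r: -r.area)[:2]
    out = np.zeros_like(mask)
    for p in props:
        out |= lab == p.label
    return out
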
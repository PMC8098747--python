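"""Integrated-intensity measurements on sum projections.

Midzone protein signal is integrated inside a rectangular box (40 px wide,
10 μm long) placed midway between the two segregating chromosome sets,
perpendicular to the spindle axis, on a sum projection of the z-stack;
the integrated value is background-subtracted and divided by the number of
z planes. Whole-spindle signal uses a polygon instead of the box. Astral
microtubule lengths are summed point-by-point along a 3-D polyline.

Background modes: ``cytoplasm_mean`` subtracts the mean of a cytoplasm
region (auto-estimated from the image border when none is given);
``line_min`` subtracts the minimum value found inside the box, the
convention used for tubulin line profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .photoactivation import estimate_background

__all__ = ["IntensityMeasurement", "sum_projection", "midzone_box_intensity",
           "whole_spindle_intensity", "astral_mt_length"]


@dataclass
class IntensityMeasurement:
    """One integrated-intensity record for one cell."""

    cell_id: str
    metric: str
    raw: float              # integrated, background-subtracted counts
    background: float       # per-pixel background that was subtracted
    n_z: int
    value: float            # raw / n_z
    normalized: float | None = None  # value / control-group mean

    def normalize(self, control_mean: float) -> "IntensityMeasurement":
        if control_mean == 0:
            raise ValueError("control mean is zero; cannot normalize")
        self.normalized = self.value / control_mean
        return self


def sum_projection(zstack: np.ndarray):
    """Sum project a Z×Y×X stack; returns (projection, n_z)."""
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim == 2:
        return zstack, 1
    if zstack.ndim != 3:
        raise ValueError(f"expected Z x Y x X stack, got {zstack.shape}")
    return zstack.sum(axis=0), zstack.shape[0]


def _box_mask(shape, center_px, axis_unit, width_px, length_px):
    """Boolean mask of a rotated rectangle centered at center_px.

    ``length`` runs perpendicular to the spindle axis (the box is laid
    across the midzone), ``width`` along it.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    dx = xx - center_px[0]
    dy = yy - center_px[1]
    u = np.asarray(axis_unit, dtype=float)
    u = u / np.linalg.norm(u)
    w = np.array([-u[1], u[0]])
    along = dx * u[0] + dy * u[1]
    across = dx * w[0] + dy * w[1]
    return (np.abs(along) <= width_px / 2.0) & \
           (np.abs(across) <= length_px / 2.0)


def midzone_box_intensity(projection: np.ndarray, n_z: int, center_px,
                          axis_unit, pixel_size: float,
                          width_px: int = 40, length_um: float = 10.0,
                          background_mode: str = "cytoplasm_mean",
                          background: float | None = None,
                          cell_id: str = "",
                          metric: str = "midzone_intensity"
                          ) -> IntensityMeasurement:
    """Integrated midzone intensity in the standard rotated box.

    The box is ``width_px`` wide along the spindle axis and ``length_um``
    long perpendicular to it, centered midway between the chromosome sets
    (``center_px``). The integrated background-subtracted signal is
    divided by ``n_z``.
    """
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    proj = np.asarray(projection, dtype=float)
    length_px = length_um / pixel_size
    mask = _box_mask(proj.shape, center_px, axis_unit, width_px, length_px)
    if not mask.any():
        raise ValueError("midzone box lies outside the image")
    # boxes partially outside simply lose area; fully inside is the norm
    edge = np.zeros_like(mask)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if (mask & edge).any():
        raise ValueError("midzone box exits the image")
    vals = proj[mask]
    if background_mode == "line_min":
        bg = float(vals.min())
    elif background_mode == "cytoplasm_mean":
        bg = float(background) if background is not None \
            else estimate_background(proj)
    else:
        raise ValueError(f"unknown background_mode {background_mode!r}")
    raw = float((vals - bg).sum())
    return IntensityMeasurement(cell_id=cell_id, metric=metric, raw=raw,
                                background=bg, n_z=n_z, value=raw / n_z)


def whole_spindle_intensity(projection: np.ndarray, n_z: int,
                            spindle_polygon: Polygon,
                            background: float | None = None,
                            cell_id: str = "",
                            metric: str = "spindle_intensity"
                            ) -> IntensityMeasurement:
    """Mean intensity inside the spindle polygon minus cytoplasm
    background, divided by the number of z planes."""
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    proj = np.asarray(projection, dtype=float)
    if spindle_polygon.is_empty:
        raise ValueError("empty spindle polygon")
    ny, nx = proj.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    inside = shapely.contains_xy(spindle_polygon, xx.ravel(), yy.ravel())
    inside = inside.reshape(proj.shape)
    if not inside.any():
        raise ValueError("spindle polygon covers no pixels")
    bg = float(background) if background is not None \
        else estimate_background(proj)
    raw = float(proj[inside].mean() - bg)
    return IntensityMeasurement(cell_id=cell_id, metric=metric, raw=raw,
                                background=bg, n_z=n_z, value=raw / n_z)


def astral_mt_length(points) -> float:
    """Length of an astral microtubule traced point-by-point in 3-D (μm).

    ``points`` is an ordered (n, 3) array of positions ~1 μm apart along
    the microtubule, from the pole-proximal end to the tip. Eligible
    microtubules are those whose tip contacts the cell membrane and that
    project away from the opposite pole; eligibility is the caller's
    responsibility, this function only sums segment lengths. Duplicate
    consecutive points contribute zero-length segments (warned).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if (seg == 0).any():
        warnings.warn("duplicate consecutive points: zero-length segments",
                      stacklevel=2)
    return float(seg.sum())
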
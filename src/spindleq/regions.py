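"""Astral / midzone / cortex partition of an anaphase cell.

The cell is divided the way the EB3 analysis defines it: each *astral*
region is enclosed by the line through its centrosome perpendicular to the
spindle long axis and by the cell boundary; the *midzone* is the rectangle
between the inner edges of the two segregating chromosome masses; the
*cortex* band is every point within ``contact_distance`` of the cell
boundary. Every point belongs to exactly one of {astral1, astral2, midzone,
other}; the cortex band is an overlay, not a fifth exclusive region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box

__all__ = ["RegionPartition", "make_anaphase_geometry", "partition_regions"]


@dataclass
class RegionPartition:
    """Deterministic geometric partition of one (or one frame of a) cell."""

    pole_points: np.ndarray  # (2, 2) μm, [pole1(x,y), pole2(x,y)]
    astral1: Polygon
    astral2: Polygon
    midzone: Polygon
    cell: Polygon
    contact_distance: float = 0.5
    frame: int | None = field(default=None)

    def __post_init__(self):
        self.pole_points = np.asarray(self.pole_points, dtype=float)
        if self.pole_points.shape != (2, 2):
            raise ValueError("pole_points must be a (2, 2) array")
        if np.allclose(self.pole_points[0], self.pole_points[1]):
            raise ValueError("degenerate spindle axis: poles coincide")

    @property
    def axis_unit(self) -> np.ndarray:
        d = self.pole_points[1] - self.pole_points[0]
        return d / np.linalg.norm(d)

    def assign(self, x, y) -> np.ndarray:
        """Region label of each point: astral1 | astral2 | midzone | other.

        Regions are pairwise disjoint by construction; boundary points are
        resolved in the fixed order midzone, astral1, astral2.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        labels = np.full(x.shape, "other", dtype=object)
        for name, poly in (("midzone", self.midzone),
                           ("astral1", self.astral1),
                           ("astral2", self.astral2)):
            if poly.is_empty:
                continue
            hit = shapely.contains_xy(poly, x, y) & (labels == "other")
            labels[hit] = name
        return labels.astype(str)

    def contains(self, x, y) -> np.ndarray:
        """True where the point lies inside the cell boundary."""
        return shapely.contains_xy(
            self.cell, np.atleast_1d(x), np.atleast_1d(y))

    def in_cortex(self, x, y) -> np.ndarray:
        """True inside the cell and within contact_distance of its boundary."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        inside = self.contains(x, y)
        pts = shapely.points(np.column_stack([x, y]))
        d = shapely.distance(pts, self.cell.exterior)
        return inside & (d <= self.contact_distance)

    def midzone_length(self) -> float:
        """Axial extent of the midzone rectangle in μm (0 if empty)."""
        if self.midzone.is_empty:
            return 0.0
        v = np.asarray(self.midzone.exterior.coords)
        proj = v @ self.axis_unit
        return float(proj.max() - proj.min())

    def sample_midzone_point(self, rng: np.random.Generator):
        """Uniform random point inside the midzone (rejection sampling)."""
        if self.midzone.is_empty:
            raise ValueError("midzone region is empty")
        xmin, ymin, xmax, ymax = self.midzone.bounds
        for _ in range(1000):
            p = (rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
            if shapely.contains_xy(self.midzone, *p):
                return p
        raise RuntimeError("could not sample a midzone point")

    def bounds(self):
        xmin, ymin, xmax, ymax = self.cell.bounds
        return (xmin, ymin), (xmax, ymax)


def make_anaphase_geometry(spindle_length: float = 14.0,
                           cell_halfaxes=(16.0, 11.0),
                           chromosome_gap: float = 6.0,
                           chromosome_halfwidth: float = 3.0,
                           contact_distance: float = 0.5) -> RegionPartition:
    """Analytic mid-anaphase geometry: elliptical cell, axis along x.

    Poles sit at ``±spindle_length / 2`` on the x axis; the midzone is the
    rectangle of half-gap ``chromosome_gap / 2`` along x and half-width
    ``chromosome_halfwidth`` along y, standing in for the space between the
    two H2B chromosome blocks.
    """
    a, b = cell_halfaxes
    half = spindle_length / 2.0
    if half >= a:
        raise ValueError("spindle longer than the cell")
    theta = np.linspace(0.0, 2.0 * np.pi, 181)[:-1]
    cell = Polygon(np.column_stack([a * np.cos(theta), b * np.sin(theta)]))
    big = max(a, b) * 2.0
    astral1 = cell.intersection(box(-big, -big, -half, big))
    astral2 = cell.intersection(box(half, -big, big, big))
    midzone = box(-chromosome_gap / 2.0, -chromosome_halfwidth,
                  chromosome_gap / 2.0, chromosome_halfwidth)
    poles = np.array([[-half, 0.0], [half, 0.0]])
    return RegionPartition(poles, astral1, astral2, midzone, cell,
                           contact_distance)


def _mask_polygon(mask: np.ndarray, pixel_size: float, origin) -> Polygon:
    """Largest closed contour of a binary mask as a polygon in μm."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask contains no closed boundary")
    contour = max(contours, key=len)  # (row, col)
    x = origin[0] + contour[:, 1] * pixel_size
    y = origin[1] + contour[:, 0] * pixel_size
    return Polygon(np.column_stack([x, y]))


def partition_regions(pole_points, chromosome_mask=None, cell_mask=None,
                      contact_distance: float = 0.5,
                      pixel_size: float = 1.0, origin=(0.0, 0.0),
                      cell_polygon: Polygon | None = None,
                      frame: int | None = None) -> RegionPartition:
    """Build a :class:`RegionPartition` from masks or a cell polygon.

    Parameters
    ----------
    pole_points : (2, 2) array
        Centrosome positions in μm.
    chromosome_mask : 2-D bool array, optional
        Binary H2B mask; its two largest connected components define the
        chromosome blocks whose facing (inner) edges bound the midzone.
        If omitted the midzone is empty.
    cell_mask : 2-D bool array, optional
        Binary cell mask; its outline becomes the cell boundary. Provide
        either this or ``cell_polygon``.
    contact_distance : float
        Width of the cortex contact band, μm.
    pixel_size, origin
        Geometry of the masks' pixel grid.
    """
    from skimage import measure

    poles = np.asarray(pole_points, dtype=float)
    if poles.shape != (2, 2):
        raise ValueError("pole_points must be a (2, 2) array")
    if np.allclose(poles[0], poles[1]):
        raise ValueError("degenerate spindle axis: poles coincide")
    if cell_polygon is None:
        if cell_mask is None:
            raise ValueError("provide cell_mask or cell_polygon")
        cell_polygon = _mask_polygon(cell_mask, pixel_size, origin)

    u = poles[1] - poles[0]
    u = u / np.linalg.norm(u)
    w = np.array([-u[1], u[0]])  # perpendicular
    center = poles.mean(axis=0)
    s_poles = (poles - center) @ u  # axial coords of the poles

    xmin, ymin, xmax, ymax = cell_polygon.bounds
    big = 2.0 * max(xmax - xmin, ymax - ymin)

    def axis_box(s0, s1, p0, p1) -> Polygon:
        corners = [center + s * u + p * w
                   for s, p in ((s0, p0), (s1, p0), (s1, p1), (s0, p1))]
        return Polygon(corners)

    astral1 = cell_polygon.intersection(
        axis_box(-big, min(s_poles), -big, big))
    astral2 = cell_polygon.intersection(
        axis_box(max(s_poles), big, -big, big))

    midzone = Polygon()
    if chromosome_mask is not None and chromosome_mask.any():
        lab = measure.label(chromosome_mask)
        props = sorted(measure.regionprops(lab), key=lambda r: -r.area)[:2]
        if len(props) == 2:
            edges, widths, reaches_pole = [], [], False
            for pr in props:
                rr, cc = np.nonzero(lab == pr.label)
                pts = np.column_stack([origin[0] + cc * pixel_size,
                                       origin[1] + rr * pixel_size]) - center
                s = pts @ u
                p = pts @ w
                # the block's edge facing the spindle center
                edges.append(s.min() if s.mean() > 0 else s.max())
                widths.append(np.abs(p).max())
                # a block extending to (or past) its pole is degenerate
                if s.min() <= min(s_poles) or s.max() >= max(s_poles):
                    reaches_pole = True
            s_lo, s_hi = sorted(edges)
            if reaches_pole or s_hi <= s_lo:
                warnings.warn("chromosome blocks touch the poles or overlap: "
                              "empty midzone", stacklevel=2)
            else:
                half_w = max(widths)
                midzone = axis_box(s_lo, s_hi, -half_w, half_w)

    return RegionPartition(poles, astral1, astral2, midzone, cell_polygon,
                           contact_distance, frame=frame)
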
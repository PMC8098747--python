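"""Core containers shared by every stage of the pipeline.

All coordinates are continuous positions in micrometers. The center of pixel
(0, 0) sits at the metadata ``origin``; x increases rightward (columns), y
increases downward (rows). Frame indices are 0-based and the time of frame
``k`` is ``k * frame_interval`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MovieMetadata", "ImageStack"]


@dataclass
class MovieMetadata:
    """Acquisition metadata attached to every image stack.

    Parameters
    ----------
    pixel_size : float
        Lateral pixel size in μm/px (83 nm on the confocal system emulated
        by the synthetic generator).
    frame_interval : float
        Time between consecutive frames in seconds.
    channel_roles : dict
        Map channel index -> biological role, e.g. ``{0: "kinetochore"}``.
        Recognized roles: kinetochore, centrosome, pa_tubulin, dna, eb3, h2b.
    origin : tuple of float
        (x, y) position in μm of the center of pixel (0, 0).
    axes : str
        Axis order declaration of the raw array ("TYX" or "TYXC").
    """

    pixel_size: float
    frame_interval: float
    channel_roles: dict = field(default_factory=dict)
    origin: tuple = (0.0, 0.0)
    axes: str = "TYX"

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise ValueError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )


@dataclass
class ImageStack:
    """A T×Y×X (optionally ×C) intensity array plus its metadata.

    Intensities are handled as floating point regardless of on-disk bit
    depth.
    """

    data: np.ndarray
    meta: MovieMetadata

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"expected TYX or TYXC array, got shape {self.data.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) * self.meta.frame_interval

    def channel(self, c: int) -> "ImageStack":
        """Extract a single channel as a TYX stack."""
        if self.data.ndim != 4:
            raise ValueError("stack has no channel axis")
        meta = replace(self.meta, axes="TYX",
                       channel_roles={0: self.meta.channel_roles.get(c, "")})
        return ImageStack(self.data[..., c], meta)

    def px_to_um(self, col: np.ndarray, row: np.ndarray):
        """Convert pixel (col, row) coordinates to μm (x, y)."""
        x0, y0 = self.meta.origin
        p = self.meta.pixel_size
        return x0 + np.asarray(col) * p, y0 + np.asarray(row) * p

    def um_to_px(self, x: np.ndarray, y: np.ndarray):
        """Convert μm (x, y) coordinates to fractional pixel (col, row)."""
        x0, y0 = self.meta.origin
        p = self.meta.pixel_size
        return (np.asarray(x) - x0) / p, (np.asarray(y) - y0) / p
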
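"""Reading and writing the formats the pipeline touches.

TIFF stacks (via :mod:`tifffile`), long-format measurement tables (CSV),
and the flat YAML configuration file that holds every analysis threshold
and window with the emulated study's values as defaults.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImageStack, MovieMetadata

__all__ = [
    "read_stack", "write_stack", "write_tables", "read_tables",
    "default_config", "load_config", "save_config", "MeasurementTable",
]

log = logging.getLogger(__name__)

#: Canonical column order of the long-format measurement table: one row per
#: cell per metric, units always recorded.
MEASUREMENT_COLUMNS = ["cell_id", "condition", "metric", "value", "units",
                       "window"]


class MeasurementTable(pd.DataFrame):
    """Long-format per-cell measurement records (a thin DataFrame)."""

    _metadata: list = []

    @property
    def _constructor(self):
        return MeasurementTable

    @classmethod
    def from_records_list(cls, records) -> "MeasurementTable":
        df = pd.DataFrame(records, columns=MEASUREMENT_COLUMNS)
        return cls(df)


def read_stack(path, pixel_size: float | None = None,
               frame_interval: float | None = None,
               channel_roles: dict | None = None,
               axes: str | None = None,
               defaults: dict | None = None) -> ImageStack:
    """Read a multi-frame TIFF into an :class:`ImageStack`.

    Metadata missing from the file is taken from the explicit overrides,
    then from ``defaults`` (e.g. a loaded config) with a logged warning.
    ``axes`` declares the on-disk order, "TYX" or "TYXC"; a 4-D file
    without a declaration raises (axis-order ambiguity).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            ij = tif.imagej_metadata or {}
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise IOError(f"unreadable TIFF file {path}: {exc}") from None
    if data.ndim == 2:
        data = data[None]
    if data.ndim not in (3, 4):
        raise IOError(f"{path}: expected a T x Y x X (x C) stack, "
                      f"got shape {data.shape}")
    if data.ndim == 4 and axes is None and ij.get("axes") is None:
        raise IOError(f"{path}: 4-D stack without an axes declaration; "
                      "pass axes='TYXC' or similar")
    axes = axes or ij.get("axes") or "TYX"
    if axes == "TCYX":
        data = np.moveaxis(data, 1, -1)
        axes = "TYXC"
    elif axes not in ("TYX", "TYXC"):
        raise IOError(f"{path}: unsupported axes order {axes!r}")

    defaults = defaults or {}
    if pixel_size is None:
        pixel_size = ij.get("pixel_size") or defaults.get("pixel_size")
        if pixel_size is None:
            raise IOError(f"{path}: pixel_size neither stored nor supplied")
        log.warning("%s: pixel_size taken from defaults (%g μm)", path,
                    pixel_size)
    if frame_interval is None:
        frame_interval = ij.get("finterval") or defaults.get("frame_interval")
        if frame_interval is None:
            raise IOError(f"{path}: frame_interval neither stored nor "
                          "supplied")
        log.warning("%s: frame_interval taken from defaults (%g s)", path,
                    frame_interval)
    meta = MovieMetadata(pixel_size=float(pixel_size),
                         frame_interval=float(frame_interval),
                         channel_roles=channel_roles or {}, axes=axes)
    return ImageStack(np.asarray(data, dtype=float), meta)


def write_stack(path, stack: ImageStack) -> Path:
    """Write an :class:`ImageStack` to an ImageJ-style TIFF."""
    path = Path(path)
    meta = {"axes": stack.meta.axes, "pixel_size": stack.meta.pixel_size,
            "finterval": stack.meta.frame_interval}
    tifffile.imwrite(path, stack.data.astype(np.float32),
                     imagej=True, metadata=meta)
    return path


def write_tables(table: pd.DataFrame, path) -> Path:
    """Write a measurement table as CSV with stable column order.

    An empty table produces a header-only file and a warning.
    """
    path = Path(path)
    cols = [c for c in MEASUREMENT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    if len(table) == 0:
        warnings.warn(f"writing empty measurement table to {path}",
                      stacklevel=2)
    try:
        table.loc[:, cols].to_csv(path, index=False, float_format="%.6g")
    except OSError as exc:
        raise IOError(f"cannot write table to {path}: {exc}") from None
    return path


def read_tables(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except OSError as exc:
        raise IOError(f"cannot read table from {path}: {exc}") from None


def default_config() -> dict:
    """Analysis defaults: the emulated study's windows and thresholds."""
    return {
        # acquisition
        "pixel_size": 0.083,           # μm/px
        "frame_interval": 15.0,        # s (0.8 s for PA assays, 1 s for EB3)
        # velocity windows, seconds from anaphase onset
        "velocity_window": [60.0, 180.0],      # default 1-3 min window
        "regression_window": [60.0, 120.0],    # alternative 60-120 s window
        "pa_window_length": 60.0,      # s after photoactivation onset
        "crispr_window": [0.0, 60.0],  # s, first minute of anaphase
        "net_elongation_horizon": 300.0,  # s (5 min)
        # onset detection
        "onset_noise_floor": None,     # μm; None -> 2x pre-onset jitter
        # tracking
        "sigma0": 1.0,                 # px, Gaussian fit seed sigma
        "max_disp": 1.0,               # μm per frame transition
        "max_gap": 1,                  # frames
        # photoactivation assay
        "profile_thickness_px": 100,
        "kymograph_thickness_px": 40,
        "edge_fraction": 0.2,          # band-edge threshold, fraction of peak
        "stability_lag": 30.0,         # s
        "sliding_window": [0.0, 30.0],  # s
        "peak_snr_min": 5.0,           # band peak must exceed k x noise sd
        # EB3 comets
        "blob_diameter": 1.0,          # μm
        "quality_threshold": 0.8,
        "contact_distance": 0.5,       # μm
        # intensity boxes
        "midzone_box_width_px": 40,
        "midzone_box_length_um": 10.0,
    }


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load the YAML config, filling gaps from :func:`default_config`."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            warnings.warn(f"unknown config keys ignored: {sorted(unknown)}",
                          stacklevel=2)
        cfg.update({k: v for k, v in user.items() if k in cfg})
    if overrides:
        cfg.update(overrides)
    return cfg


def save_config(cfg: dict, path) -> Path:
    """Echo a config (e.g. simulation provenance) as flat YAML."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, default_flow_style=False, sort_keys=True)
    return path
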
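"""Ground-truthed synthetic anaphase-spindle movies.

This module generates the tracked objects and rendered image stacks that the
quantification stages are validated against: separating spindle poles with
sister-kinetochore pairs (anaphase A poleward motion plus anaphase B pole
separation), a photoactivated tubulin band whose antiparallel halves slide
apart while the signal decays by turnover and bleaching, and EB3 plus-end
comets nucleating, moving and dying in astral and midzone regions.

Every simulation returns a :class:`GroundTruth` carrying the exact object
positions (μm) and the true parameter values, so that each estimator in the
pipeline can be scored by parameter recovery without any external data.

Conventions: continuous positions in μm, spindle axis along x, spindle
center at the origin; time of frame k is ``k * frame_interval`` seconds;
identical parameters and seed give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .core import ImageStack, MovieMetadata
from .regions import RegionPartition, make_anaphase_geometry

__all__ = [
    "SpindleSimParams",
    "PABandSimParams",
    "CometSimParams",
    "RenderOptics",
    "GroundTruth",
    "simulate_spindle_tracks",
    "render_frames",
    "simulate_pa_band",
    "simulate_comets",
    "peak_counts",
    "flux_for_snr",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class SpindleSimParams:
    """Kinematic parameters of a synthetic anaphase spindle movie.

    Parameters
    ----------
    v_B : float
        Pole-separation (spindle elongation) velocity after anaphase onset,
        μm/min. The control condition emulated here elongates at
        ~2.4 μm/min; double motor perturbations at ~0.35-0.55 μm/min.
    v_A : float
        Poleward kinetochore-to-pole velocity (anaphase A), μm/min. The
        sister-centroid distance therefore grows at ``v_B + 2 * v_A``.
    onset_time : float
        Anaphase onset, seconds from movie start.
    initial_pole_distance : float
        Metaphase spindle length (pole-to-pole), μm.
    initial_sister_distance : float
        Sister-kinetochore centroid distance at onset, μm.
    n_kt_pairs : int
        Number of sister-kinetochore pairs.
    frame_interval, n_frames : float, int
        Sampling cadence (s) and movie length (15 s cadence, ~8 min here).
    pixel_size : float
        μm/px used when rendering (83 nm camera pixels).
    jitter_sd : float
        Gaussian positional noise (μm) added to every coordinate after the
        trajectories are built; emulates localization error.
    min_kt_pole_distance : float
        Kinetochores stall this far from their pole (μm); anaphase A motion
        is clamped there.
    seed : int
        Seed for all randomness of this simulation.
    """

    v_B: float = 2.36
    v_A: float = 0.5
    onset_time: float = 60.0
    initial_pole_distance: float = 12.0
    initial_sister_distance: float = 1.0
    n_kt_pairs: int = 6
    frame_interval: float = 15.0
    n_frames: int = 32
    pixel_size: float = 0.083
    jitter_sd: float = 0.05
    min_kt_pole_distance: float = 0.8
    seed: int = 0

    def validate(self):
        if self.v_B < 0:
            raise ValueError(f"v_B must be >= 0, got {self.v_B}")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        span = (self.n_frames - 1) * self.frame_interval
        if not (0 <= self.onset_time <= span):
            raise ValueError(
                f"onset_time {self.onset_time}s outside movie span [0, {span}]s"
            )
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        k0 = (self.initial_pole_distance - self.initial_sister_distance) / 2.0
        if k0 <= 0:
            raise ValueError(
                "non-physical geometry: initial sister distance "
                f"{self.initial_sister_distance} μm >= pole distance "
                f"{self.initial_pole_distance} μm"
            )
        if self.min_kt_pole_distance > k0:
            raise ValueError(
                "non-physical geometry: min_kt_pole_distance exceeds the "
                "initial kinetochore-to-pole distance"
            )


@dataclass
class PABandSimParams:
    """Parameters of the photoactivated tubulin-band assay movie.

    The activated band is laid down perpendicular to the spindle axis as a
    line of ``n_points`` activation spots (10 in the emulated assay). Its
    two antiparallel halves translate apart at ``±v_slide / 2`` along the
    axis while the activated signal decays: turnover leaves a fraction
    ``survival_30s`` of the (bleach-corrected) signal after 30 s, and
    photobleaching multiplies everything by ``exp(-bleach_rate * t)``.
    Movies are sampled at 0.8 s for 200 frames like the emulated assay.
    """

    v_slide: float = 1.5
    survival_30s: float = 0.7
    bleach_rate: float = 0.0
    band_thickness: float = 0.5
    n_points: int = 10
    spot_spacing: float = 0.5
    background_level: float = 10.0
    frame_interval: float = 0.8
    n_frames: int = 200
    seed: int = 0

    def validate(self):
        if not (0.0 <= self.survival_30s <= 1.0):
            raise ValueError("survival_30s must lie in [0, 1]")
        if self.v_slide < 0:
            raise ValueError("v_slide must be >= 0")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")
        if self.band_thickness <= 0 or self.spot_spacing <= 0:
            raise ValueError("band_thickness and spot_spacing must be > 0")


@dataclass
class CometSimParams:
    """Parameters of the EB3 plus-end comet movie.

    Comets nucleate at Poisson times (per-region rates in comets/s), move at
    ``v_comet`` — radially outward from their pole in the astral regions,
    axially in the midzone — and disappear after exponentially distributed
    lifetimes. A comet whose tip comes within the geometry's
    ``contact_distance`` of the cell boundary is recorded as a cortex
    contact.
    """

    nucleation_rate_astral: float = 1.0
    nucleation_rate_midzone: float = 0.5
    v_comet: float = 20.0
    mean_lifetime: float = 8.0
    comet_sigma: float = 0.3
    frame_interval: float = 1.0
    n_frames: int = 60
    seed: int = 0

    def validate(self):
        for name in ("nucleation_rate_astral", "nucleation_rate_midzone",
                     "v_comet", "mean_lifetime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.comet_sigma <= 0:
            raise ValueError("comet_sigma must be > 0")


@dataclass
class RenderOptics:
    """Optical and camera model used by :func:`render_frames`.

    ``flux`` is the integrated signal per object per frame (counts); noise
    is Poisson shot noise on signal plus background, followed by additive
    Gaussian read noise. ``background`` models diffuse fluorescence, so the
    per-frame bleach factor ``exp(-bleach_rate * t)`` applies to it as well;
    read noise is unaffected. If ``shape``/``origin`` are omitted the field
    of view is fitted around the object positions with a margin.
    """

    psf_sigma: float = 0.11
    background: float = 10.0
    flux: float = 1000.0
    read_noise_sd: float = 2.0
    noise: bool = True
    bleach_rate: float = 0.0
    shape: tuple | None = None
    origin: tuple | None = None
    margin: float = 1.5
    seed: int | None = None


@dataclass
class GroundTruth:
    """True object trajectories plus the generating parameter values.

    ``tracks`` is a long-format table with columns ``object_id``, ``label``,
    ``frame``, ``t_s``, ``x_um``, ``y_um`` and, where relevant, per-row
    rendering columns (``weight``, ``width_x_um``, ``width_y_um``). ``info``
    holds the true quantities each estimator should recover (velocities,
    survival fraction, band widths, per-region counts, ...).
    """

    tracks: pd.DataFrame
    pixel_size: float
    frame_interval: float
    info: dict = field(default_factory=dict)

    def positions(self, frame: int):
        """(x, y) μm arrays of all objects present in one frame."""
        sub = self.tracks[self.tracks["frame"] == frame]
        return sub["x_um"].to_numpy(), sub["y_um"].to_numpy()

    def track(self, object_id: str) -> pd.DataFrame:
        return self.tracks[self.tracks["object_id"] == object_id]


def peak_counts(flux: float, psf_sigma: float, pixel_size: float) -> float:
    """Approximate peak pixel value of a rendered spot of given flux."""
    return flux * pixel_size**2 / (2.0 * np.pi * psf_sigma**2)


def flux_for_snr(snr: float, optics: RenderOptics, pixel_size: float) -> float:
    """Integrated flux giving peak SNR ``snr``.

    SNR is defined as peak signal over the background noise standard
    deviation ``sqrt(background + read_noise_sd**2)``.
    """
    noise_sd = np.sqrt(optics.background + optics.read_noise_sd**2)
    peak = snr * noise_sd
    return peak * 2.0 * np.pi * optics.psf_sigma**2 / pixel_size**2


def simulate_spindle_tracks(params: SpindleSimParams) -> GroundTruth:
    """Generate pole and sister-kinetochore trajectories.

    The pole-to-pole distance is constant before ``onset_time`` and then
    grows at exactly ``v_B``; each kinetochore approaches its pole at
    ``v_A`` (clamped at ``min_kt_pole_distance``), so the sister-centroid
    distance grows at ``v_B + 2 * v_A`` while unclamped. Gaussian jitter of
    sd ``jitter_sd`` is added to every coordinate afterwards.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.n_frames) * params.frame_interval
    dt_anaphase = np.maximum(t - params.onset_time, 0.0)

    L = params.initial_pole_distance + params.v_B / 60.0 * dt_anaphase
    k0 = (params.initial_pole_distance - params.initial_sister_distance) / 2.0
    k = np.maximum(k0 - params.v_A / 60.0 * dt_anaphase,
                   params.min_kt_pole_distance)

    rows = []
    frames = np.arange(params.n_frames)
    for sign, pid in ((-1.0, "pole_1"), (1.0, "pole_2")):
        rows.append(pd.DataFrame({
            "object_id": pid, "label": "pole", "frame": frames, "t_s": t,
            "x_um": sign * L / 2.0, "y_um": 0.0,
        }))
    y_offsets = rng.uniform(-1.5, 1.5, size=params.n_kt_pairs)
    for i in range(params.n_kt_pairs):
        for sign, suffix in ((-1.0, "a"), (1.0, "b")):
            rows.append(pd.DataFrame({
                "object_id": f"kt_{i}_{suffix}", "label": "kinetochore",
                "frame": frames, "t_s": t,
                "x_um": sign * (L / 2.0 - k), "y_um": y_offsets[i],
            }))
    tracks = pd.concat(rows, ignore_index=True)

    if params.jitter_sd > 0:
        tracks["x_um"] += rng.normal(0.0, params.jitter_sd, len(tracks))
        tracks["y_um"] += rng.normal(0.0, params.jitter_sd, len(tracks))

    info = {
        "n_frames": params.n_frames,
        "v_B": params.v_B,
        "v_A": params.v_A,
        "v_sister": params.v_B + 2.0 * params.v_A,
        "onset_time": params.onset_time,
        "onset_frame": int(np.searchsorted(t, params.onset_time, "right") - 1),
        "pole_distance": L,
        "sister_distance": L - 2.0 * k,
        "kt_pole_distance": k,
        "t_s": t,
        "params": params,
    }
    return GroundTruth(tracks, params.pixel_size, params.frame_interval, info)


def _axis_profile(edges_um, centers, widths, sigma):
    """Pixel-integrated 1-D profiles (unit mass) for many objects.

    Each object is a unit-mass box of full width ``widths[i]`` centered at
    ``centers[i]``, convolved with a Gaussian PSF of sd ``sigma``; a zero
    width degenerates to a pure Gaussian. Returns array (n_objects,
    n_pixels) of per-pixel integrals over the bins defined by ``edges_um``.
    """
    e = np.asarray(edges_um)[None, :]
    c = np.asarray(centers, dtype=float)[:, None]
    w = np.asarray(widths, dtype=float)[:, None]
    out = np.empty((c.shape[0], e.shape[1] - 1))
    point = (w[:, 0] <= 0)
    if point.any():
        cdf = 0.5 * (1.0 + erf((e - c[point]) / (sigma * _SQRT2)))
        out[point] = np.diff(cdf, axis=1)
    box = ~point
    if box.any():
        s = sigma * _SQRT2

        def _a(u):
            return u * erf(u) + np.exp(-np.square(u)) / np.sqrt(np.pi)

        a = c[box] - w[box] / 2.0
        b = c[box] + w[box] / 2.0
        cdf = 0.5 * s * (_a((e - a) / s) - _a((e - b) / s)) / w[box]
        out[box] = np.diff(cdf, axis=1)
    return out


def render_frames(truth: GroundTruth, optics: RenderOptics | None = None) -> ImageStack:
    """Render ground-truth objects into a noisy image stack.

    Each object becomes a 2-D (generally Gaussian) spot of sd
    ``optics.psf_sigma`` integrated over the pixel grid; rows may carry
    ``weight`` (per-frame amplitude factor) and ``width_x_um``/
    ``width_y_um`` (PSF-smoothed box extents, used for the photoactivated
    band). Poisson shot noise plus Gaussian read noise is applied when
    ``optics.noise``; a per-frame exponential bleach factor when
    ``optics.bleach_rate > 0``.
    """
    optics = optics or RenderOptics()
    px = truth.pixel_size
    if optics.psf_sigma < px:
        raise ValueError(
            f"psf_sigma {optics.psf_sigma} μm is below one pixel ({px} μm): "
            "undersampled rendering"
        )
    tr = truth.tracks
    n_frames = truth.info.get("n_frames")
    if n_frames is None:
        n_frames = int(tr["frame"].max()) + 1 if len(tr) else 0
    n_frames = int(n_frames)
    if optics.origin is None or optics.shape is None:
        if not len(tr):
            raise ValueError("cannot infer field of view from empty truth")
        m = optics.margin
        x0 = tr["x_um"].min() - m
        y0 = tr["y_um"].min() - m
        nx = int(np.ceil((tr["x_um"].max() + m - x0) / px)) + 1
        ny = int(np.ceil((tr["y_um"].max() + m - y0) / px)) + 1
        origin = (float(x0), float(y0))
        shape = (ny, nx)
    else:
        origin = tuple(optics.origin)
        shape = tuple(optics.shape)
        x_hi = origin[0] + (shape[1] - 1) * px
        y_hi = origin[1] + (shape[0] - 1) * px
        if ((tr["x_um"] < origin[0]) | (tr["x_um"] > x_hi)
                | (tr["y_um"] < origin[1]) | (tr["y_um"] > y_hi)).any():
            raise ValueError("true positions fall outside the field of view")

    ny, nx = shape
    x_edges = origin[0] + (np.arange(nx + 1) - 0.5) * px
    y_edges = origin[1] + (np.arange(ny + 1) - 0.5) * px
    seed = truth.info.get("params").seed if optics.seed is None and \
        "params" in truth.info else optics.seed
    rng = np.random.default_rng(0 if seed is None else seed)

    has_weight = "weight" in tr.columns
    has_wx = "width_x_um" in tr.columns
    has_wy = "width_y_um" in tr.columns
    has_flux = "flux" in tr.columns
    data = np.empty((n_frames, ny, nx))
    times = np.arange(n_frames) * truth.frame_interval
    by_frame = dict(tuple(tr.groupby("frame")))
    for f in range(n_frames):
        bleach = np.exp(-optics.bleach_rate * times[f])
        img = np.full((ny, nx), optics.background * bleach)
        sub = by_frame.get(f)
        if sub is not None and len(sub):
            wx = sub["width_x_um"].to_numpy() if has_wx else np.zeros(len(sub))
            wy = sub["width_y_um"].to_numpy() if has_wy else np.zeros(len(sub))
            px_profile = _axis_profile(x_edges, sub["x_um"].to_numpy(), wx,
                                       optics.psf_sigma)
            py_profile = _axis_profile(y_edges, sub["y_um"].to_numpy(), wy,
                                       optics.psf_sigma)
            amp = np.full(len(sub), optics.flux)
            if has_flux:
                amp = sub["flux"].to_numpy()
            if has_weight:
                amp = amp * sub["weight"].to_numpy()
            amp = amp * bleach
            img += np.einsum("k,ki,kj->ij", amp, py_profile, px_profile)
        if optics.noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
            img += rng.normal(0.0, optics.read_noise_sd, img.shape)
        data[f] = img

    meta = MovieMetadata(pixel_size=px, frame_interval=truth.frame_interval,
                         origin=origin, axes="TYX")
    return ImageStack(data, meta)


def simulate_pa_band(params: PABandSimParams,
                     spindle: SpindleSimParams | None = None,
                     optics: RenderOptics | None = None):
    """Simulate the photoactivated tubulin band and render its movie.

    The band is placed at the spindle midzone center, perpendicular to the
    pole-pole axis, as ``n_points`` activation spots along y. Each spot
    splits into two PSF-smoothed rectangular half-bands (full axial width
    ``band_thickness``) translating apart at ``±v_slide / 2``, so the true
    band extent is ``band_thickness + v_slide * t / 60``. Turnover scales
    the activated signal by ``survival_30s ** (t / 30)``; bleaching by
    ``exp(-bleach_rate * t)`` on top. Returns ``(ImageStack, GroundTruth)``.
    """
    params.validate()
    spindle = spindle or SpindleSimParams()
    if optics is None:
        optics = RenderOptics(background=params.background_level,
                              seed=params.seed)
    optics.bleach_rate = params.bleach_rate

    # inter-chromosome gap ~30 s after onset, when the assay starts
    k0 = (spindle.initial_pole_distance - spindle.initial_sister_distance) / 2
    gap = spindle.initial_sister_distance + \
        (spindle.v_B + 2 * spindle.v_A) / 60.0 * 30.0
    if params.band_thickness > gap:
        warnings.warn(
            f"activated band ({params.band_thickness} μm) is wider than the "
            f"inter-chromosome gap ({gap:.2f} μm); rendering anyway",
            stacklevel=2,
        )
    del k0

    t = np.arange(params.n_frames) * params.frame_interval
    frames = np.arange(params.n_frames)
    half_v = params.v_slide / 60.0 / 2.0  # μm/s per half-band
    if params.survival_30s > 0:
        weight = params.survival_30s ** (t / 30.0)
    else:
        weight = np.where(t == 0, 1.0, 0.0)
    y_pts = (np.arange(params.n_points) -
             (params.n_points - 1) / 2.0) * params.spot_spacing

    rows = []
    for j, yj in enumerate(y_pts):
        for sign, half in ((-1.0, 1), (1.0, 2)):
            rows.append(pd.DataFrame({
                "object_id": f"pa_p{j}_h{half}", "label": f"pa_half{half}",
                "frame": frames, "t_s": t,
                "x_um": sign * half_v * t, "y_um": yj,
                "weight": weight,
                "width_x_um": params.band_thickness,
                "width_y_um": params.spot_spacing,
                "flux": optics.flux / 2.0,
            }))
    tracks = pd.concat(rows, ignore_index=True)

    true_widths = params.band_thickness + params.v_slide / 60.0 * t
    info = {
        "n_frames": params.n_frames,
        "v_slide": params.v_slide,
        "survival_30s": params.survival_30s,
        "bleach_rate": params.bleach_rate,
        "true_widths": true_widths,
        "t_s": t,
        "band_center": (0.0, 0.0),
        "params": params,
    }
    truth = GroundTruth(tracks, spindle.pixel_size, params.frame_interval,
                        info)
    stack = render_frames(truth, optics)
    return stack, truth


def simulate_comets(params: CometSimParams,
                    geometry: RegionPartition | None = None,
                    optics: RenderOptics | None = None):
    """Simulate EB3 comets in astral and midzone regions and render them.

    Astral comets nucleate near their pole and move radially outward (away
    from the other pole); midzone comets nucleate inside the midzone
    rectangle and move axially in either direction. Lifetimes are
    exponential with mean ``mean_lifetime``; a comet is removed when it
    reaches the cell boundary, and any frame in which its tip lies within
    ``geometry.contact_distance`` of the boundary is flagged as a cortex
    contact. Returns ``(ImageStack, GroundTruth)``.
    """
    params.validate()
    geometry = geometry or make_anaphase_geometry()
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    T = params.n_frames * dt
    v = params.v_comet / 60.0  # μm/s
    poles = np.asarray(geometry.pole_points, dtype=float)
    axis_dir = poles[1] - poles[0]
    axis_dir = axis_dir / np.linalg.norm(axis_dir)

    births = []  # (t_birth, lifetime, x0, y0, ux, uy, birth_region)
    for region, rate in (("astral", params.nucleation_rate_astral),
                         ("midzone", params.nucleation_rate_midzone)):
        n = rng.poisson(rate * T)
        t_birth = np.sort(rng.uniform(0.0, T, n))
        life = rng.exponential(params.mean_lifetime, n)
        for tb, lf in zip(t_birth, life):
            if region == "astral":
                side = rng.integers(2)
                pole = poles[side]
                outward = axis_dir * (1.0 if side == 1 else -1.0)
                theta = rng.uniform(-np.pi / 2, np.pi / 2)
                base = np.arctan2(outward[1], outward[0])
                u = np.array([np.cos(base + theta), np.sin(base + theta)])
                r0 = rng.uniform(0.3, 2.5)
                p0 = pole + u * r0
                births.append((tb, lf, p0[0], p0[1], u[0], u[1],
                               f"astral{side + 1}"))
            else:
                x0, y0 = geometry.sample_midzone_point(rng)
                sign = 1.0 if rng.integers(2) else -1.0
                births.append((tb, lf, x0, y0, sign * axis_dir[0],
                               sign * axis_dir[1], "midzone"))

    rows = []
    n_birth = {"astral": 0, "midzone": 0}
    for i, (tb, lf, x0, y0, ux, uy, breg) in enumerate(births):
        n_birth["astral" if breg.startswith("astral") else "midzone"] += 1
        f0 = int(np.ceil(tb / dt))
        f1 = int(np.floor(min(tb + lf, T - dt * 0.5) / dt))
        if f1 < f0:
            continue
        ts = np.arange(f0, f1 + 1) * dt
        xs = x0 + ux * v * (ts - tb)
        ys = y0 + uy * v * (ts - tb)
        inside = geometry.contains(xs, ys)
        # comet dies at the cell boundary: truncate at first exit
        if not inside.all():
            stop = int(np.argmin(inside))
            if stop == 0:
                continue
            ts, xs, ys = ts[:stop], xs[:stop], ys[:stop]
        contact = geometry.in_cortex(xs, ys)
        rows.append(pd.DataFrame({
            "object_id": f"comet_{i}", "label": "comet",
            "frame": (ts / dt).round().astype(int), "t_s": ts,
            "x_um": xs, "y_um": ys, "birth_region": breg,
            "region": geometry.assign(xs, ys), "contact": contact,
        }))

    cols = ["object_id", "label", "frame", "t_s", "x_um", "y_um",
            "birth_region", "region", "contact"]
    tracks = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=cols))

    frames = np.arange(params.n_frames)
    counts = pd.DataFrame({
        "frame": frames,
        **{r: [int(((tracks["frame"] == f) & (tracks["region"] == r)).sum())
               for f in frames]
           for r in ("astral1", "astral2", "midzone", "other")},
        "cortex_contacts": [
            int(((tracks["frame"] == f) & tracks["contact"]).sum())
            for f in frames],
    })
    info = {
        "n_frames": params.n_frames,
        "region_counts": counts,
        "n_nucleated": n_birth,
        "expected_nucleations": {
            "astral": params.nucleation_rate_astral * T,
            "midzone": params.nucleation_rate_midzone * T,
        },
        "v_comet": params.v_comet,
        "geometry": geometry,
        "params": params,
    }
    pixel_size = 0.083
    truth = GroundTruth(tracks, pixel_size, params.frame_interval, info)

    if optics is None:
        optics = RenderOptics(psf_sigma=params.comet_sigma, seed=params.seed)
    else:
        optics.psf_sigma = params.comet_sigma
    if optics.origin is None or optics.shape is None:
        (xmin, ymin), (xmax, ymax) = geometry.bounds()
        m = optics.margin
        optics.origin = (xmin - m, ymin - m)
        optics.shape = (int(np.ceil((ymax - ymin + 2 * m) / pixel_size)) + 1,
                        int(np.ceil((xmax - xmin + 2 * m) / pixel_size)) + 1)
    if len(tracks) == 0:
        meta = MovieMetadata(pixel_size=pixel_size, frame_interval=dt,
                             origin=optics.origin)
        data = np.full((params.n_frames, *optics.shape),
                       float(optics.background))
        if optics.noise:
            nrng = np.random.default_rng(params.seed)
            data = nrng.poisson(data).astype(float)
            data += nrng.normal(0.0, optics.read_noise_sd, data.shape)
        return ImageStack(data, meta), truth
    stack = render_frames(truth, optics)
    return stack, truth
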
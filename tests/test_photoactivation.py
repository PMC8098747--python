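"""Photoactivation assay: profiles, stability ratio, band width, sliding."""

import numpy as np
import pytest
from scipy.ndimage import rotate

from spindleq.core import ImageStack, MovieMetadata
from spindleq.photoactivation import (band_width, build_kymograph,
                                      default_axis_line, extract_profile,
                                      fit_band_widths, pa_assay,
                                      sliding_velocity, stability_ratio)
from spindleq.simulate import (PABandSimParams, RenderOptics, flux_for_snr,
                               simulate_pa_band)

PX = 0.083


def stack_from(frames, frame_interval=0.8):
    meta = MovieMetadata(pixel_size=PX, frame_interval=frame_interval)
    return ImageStack(np.asarray(frames, dtype=float), meta)


def band_frame(shape=(80, 80), center_col=40.0, width_px=12,
               amp=50.0, background=5.0, sigma_px=1.5):
    """Frame with a vertical PSF-smoothed rectangular band."""
    from scipy.special import erf
    cols = np.arange(shape[1])
    a = center_col - width_px / 2.0
    b = center_col + width_px / 2.0
    s = sigma_px * np.sqrt(2.0)
    profile = 0.5 * (erf((cols - a) / s) - erf((cols - b) / s))
    return background + amp * np.tile(profile, (shape[0], 1))


def hline(stack, row=None):
    ny, nx = stack.data.shape[1:3]
    r = (ny - 1) / 2.0 if row is None else row
    x0, y0 = stack.px_to_um(2, r)
    x1, _ = stack.px_to_um(nx - 3, r)
    return ((float(x0), float(y0)), (float(x1), float(y0)))


class TestExtractProfile:
    def test_uniform_image_gives_zero_profile(self):
        st = stack_from([np.full((60, 60), 7.0)])
        prof = extract_profile(st, 0, hline(st), thickness_px=20)
        assert np.allclose(prof.intensity, 0.0)
        assert prof.background == pytest.approx(7.0)

    def test_band_peak_recovered(self):
        st = stack_from([band_frame(amp=50.0, background=5.0)])
        prof = extract_profile(st, 0, hline(st), thickness_px=20)
        assert prof.peak() == pytest.approx(50.0, rel=0.02)

    def test_line_outside_frame_rejected(self):
        st = stack_from([np.zeros((30, 30))])
        with pytest.raises(ValueError, match="exits"):
            extract_profile(st, 0, ((-5.0, 0.0), (10.0, 0.0)))

    def test_rotation_invariance(self):
        """Profile along a rotated line in a rotated image matches the
        unrotated case within interpolation tolerance."""
        frame = band_frame((120, 120), center_col=60.0, background=5.0)
        st = stack_from([frame])
        prof0 = extract_profile(st, 0, hline(st), thickness_px=30,
                                background=5.0)
        angle = 17.0
        rot = rotate(frame, angle, reshape=False, order=1, mode="nearest")
        st_rot = stack_from([rot])
        # rotate the line around the image center
        th = np.deg2rad(angle)
        cx = cy = (120 - 1) / 2.0 * PX
        (xa, ya), (xb, yb) = hline(st, row=(120 - 1) / 2.0)

        def rot_pt(x, y):
            dx, dy = x - cx, y - cy
            return (cx + dx * np.cos(th) + dy * np.sin(th),
                    cy - dx * np.sin(th) + dy * np.cos(th))

        line_rot = (rot_pt(xa, ya), rot_pt(xb, yb))
        prof1 = extract_profile(st_rot, 0, line_rot, thickness_px=30,
                                background=5.0)
        n = min(prof0.intensity.size, prof1.intensity.size)
        a, b = prof0.intensity[:n], prof1.intensity[:n]
        assert np.abs(a - b).max() <= 0.02 * a.max()


class TestStabilityRatio:
    def test_no_decay_gives_unity(self):
        frames = [band_frame()] * 45
        st = stack_from(frames)
        corrected, raw, _ = stability_ratio(st, hline(st), background=5.0,
                                            bleach_correction=False)
        assert raw == pytest.approx(1.0, abs=1e-9)
        assert corrected == pytest.approx(1.0, abs=1e-9)

    def test_halved_signal_gives_half(self):
        f0 = band_frame(background=0.0)
        frames = [f0] * 38 + [0.5 * f0] * 7
        st = stack_from(frames)
        _, raw, _ = stability_ratio(st, hline(st), background=0.0,
                                    bleach_correction=False, frame_avg=1)
        assert raw == pytest.approx(0.5, abs=1e-6)

    def test_generator_survival_recovered_noiselessly(self):
        pa = PABandSimParams(v_slide=0.0, survival_30s=0.7, bleach_rate=0.0,
                             n_frames=45)
        st, _ = simulate_pa_band(pa, optics=RenderOptics(noise=False,
                                                         background=10.0))
        corrected, _, _ = stability_ratio(st, default_axis_line(st))
        assert corrected == pytest.approx(0.70, abs=0.02)

    def test_bleach_correction_separates_turnover_from_bleaching(self):
        pa = PABandSimParams(v_slide=0.0, survival_30s=0.8,
                             bleach_rate=0.005, n_frames=45)
        st, _ = simulate_pa_band(pa, optics=RenderOptics(noise=False,
                                                         background=20.0))
        corrected, raw, bleach = stability_ratio(st, default_axis_line(st))
        assert corrected == pytest.approx(0.8, abs=0.02)
        assert raw < corrected
        assert bleach == pytest.approx(np.exp(-0.005 * 30.4), abs=0.01)

    def test_zero_signal_rejected(self):
        st = stack_from([np.zeros((60, 60))] * 45)
        with pytest.raises(ValueError):
            stability_ratio(st, hline(st), background=0.0)


class TestBandWidth:
    def test_rectangular_band_width_within_one_pixel(self):
        st = stack_from([band_frame(width_px=24, sigma_px=1.4)])
        w = band_width(st, 0, hline(st), edge_fraction=0.5, background=5.0)
        assert w == pytest.approx(24 * PX, abs=1.5 * PX)

    def test_gaussian_band_fwhm_closed_form(self):
        # Gaussian band sd s: width at half peak = 2 s sqrt(2 ln 2)
        cols = np.arange(120)
        s_px = 9.0
        frame = 2.0 + 80.0 * np.exp(-(cols - 60.0) ** 2 / (2 * s_px**2))
        st = stack_from([np.tile(frame, (60, 1))])
        w = band_width(st, 0, hline(st), edge_fraction=0.5, background=2.0,
                       smooth_px=0.0)
        expected = 2.0 * s_px * PX * np.sqrt(2 * np.log(2))
        assert w == pytest.approx(expected, rel=0.02)

    def test_empty_frame_gives_missing_value(self):
        rng = np.random.default_rng(0)
        st = stack_from([rng.normal(10, 1, (60, 60))])
        assert np.isnan(band_width(st, 0, hline(st)))

    def test_width_monotone_in_true_width(self):
        widths = []
        for wpx in (8, 16, 28, 40):
            st = stack_from([band_frame(width_px=wpx)])
            widths.append(band_width(st, 0, hline(st), background=5.0))
        assert all(np.diff(widths) > 0)


class TestSlidingVelocity:
    def test_constant_widths_give_zero(self):
        t = np.arange(40) * 0.8
        est = sliding_velocity(t, np.full(40, 1.0))
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_unit_conversion(self):
        # L(t) = 1 + 0.02 t μm (t in s) -> 1.2 μm/min
        t = np.arange(40) * 0.8
        est = sliding_velocity(t, 1.0 + 0.02 * t)
        assert est.value == pytest.approx(1.2, abs=1e-9)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            sliding_velocity(np.arange(5) * 0.8, np.ones(5))

    def test_template_fit_exact_on_noiseless_movie(self):
        for v in (0.0, 0.7, 1.8):
            pa = PABandSimParams(v_slide=v, survival_30s=0.8, n_frames=45)
            st, _ = simulate_pa_band(pa, optics=RenderOptics(
                noise=False, background=10.0))
            t, w = fit_band_widths(st)
            est = sliding_velocity(t, w)
            assert est.value == pytest.approx(v, abs=0.02)

    def test_sliding_invariant_under_17_degree_rotation(self):
        pa = PABandSimParams(v_slide=1.5, survival_30s=0.85, n_frames=45,
                             seed=3)
        optics = RenderOptics(background=20.0, seed=3)
        optics.flux = flux_for_snr(15, optics, PX)
        optics.margin = 3.0
        st, _ = simulate_pa_band(pa, optics=optics)
        t0, w0 = fit_band_widths(st)
        v0 = sliding_velocity(t0, w0).value

        angle = 17.0
        th = np.deg2rad(angle)
        ny, nx = st.data.shape[1:]
        rot = np.stack([rotate(f, angle, reshape=False, order=1,
                               mode="nearest") for f in st.data])
        st_rot = ImageStack(rot, st.meta)
        cx, cy = st.px_to_um((nx - 1) / 2.0, (ny - 1) / 2.0)
        (xa, ya), (xb, yb) = default_axis_line(st)

        def rot_pt(x, y):
            dx, dy = x - cx, y - cy
            return (cx + dx * np.cos(th) + dy * np.sin(th),
                    cy - dx * np.sin(th) + dy * np.cos(th))

        line_rot = (rot_pt(xa, ya), rot_pt(xb, yb))
        t1, w1 = fit_band_widths(st_rot, axis_line=line_rot)
        v1 = sliding_velocity(t1, w1).value
        assert abs(v1 - v0) <= 0.02 * max(abs(v0), 1.0)


class TestKymograph:
    def test_static_spot_makes_vertical_stripe(self):
        frame = band_frame(width_px=4, center_col=40.0)
        st = stack_from([frame] * 10)
        kym = build_kymograph(st, hline(st), thickness_px=10)
        peaks = kym.data.argmax(axis=1)
        assert np.ptp(peaks) == 0

    def test_moving_spot_slope_matches_velocity(self):
        frames = [band_frame(width_px=4, center_col=20.0 + 2.0 * k)
                  for k in range(20)]
        st = stack_from(frames, frame_interval=1.0)
        kym = build_kymograph(st, hline(st), thickness_px=10)
        peaks = kym.data.argmax(axis=1).astype(float)
        slope_px = np.polyfit(np.arange(20), peaks, 1)[0]
        v = slope_px * PX * 60.0  # μm/min
        assert v == pytest.approx(2.0 * PX * 60.0, rel=0.02)

    def test_pa_wedge_edges_separate_at_half_v_slide(self):
        """The photoactivated wedge's half-edges move apart at ±v/2."""
        pa = PABandSimParams(v_slide=1.0, survival_30s=1.0, n_frames=100)
        st, _ = simulate_pa_band(pa, optics=RenderOptics(noise=False,
                                                         background=5.0))
        kym = build_kymograph(st, default_axis_line(st), thickness_px=40)
        # edge positions at 20% of each row's peak, outermost crossings
        lows, highs = [], []
        for row in kym.data[50:]:  # halves resolved in later frames
            prof = np.clip(row - 5.0, 0, None)
            thr = 0.2 * prof.max()
            above = np.flatnonzero(prof > thr)
            lows.append(above[0])
            highs.append(above[-1])
        t = np.arange(50, 100) * 0.8
        slope_low = np.polyfit(t, np.array(lows) * PX, 1)[0] * 60.0
        slope_high = np.polyfit(t, np.array(highs) * PX, 1)[0] * 60.0
        assert slope_low == pytest.approx(-0.5, abs=0.12)
        assert slope_high == pytest.approx(0.5, abs=0.12)


def test_pa_assay_combined_result_consistency():
    pa = PABandSimParams(v_slide=1.0, survival_30s=0.8, bleach_rate=0.003,
                         n_frames=45, seed=6, background_level=20.0)
    optics = RenderOptics(background=20.0, seed=6)
    optics.flux = flux_for_snr(12, optics, PX)
    st, _ = simulate_pa_band(pa, optics=optics)
    res = pa_assay(st, profile_thickness_px=56)
    assert res.sliding_velocity.value == pytest.approx(1.0, rel=0.15)
    assert res.stability_ratio == pytest.approx(0.8, abs=0.1)
    assert res.stability_ratio_raw < res.stability_ratio  # bleach removed
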
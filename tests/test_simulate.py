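"""Generator correctness: kinematics, rendering, signal bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from spindleq.simulate import (CometSimParams, GroundTruth, PABandSimParams,
                               RenderOptics, SpindleSimParams,
                               simulate_comets, simulate_pa_band,
                               simulate_spindle_tracks)


class TestSpindleKinematics:
    def test_pole_distance_linear_after_onset(self):
        p = SpindleSimParams(v_B=2.0, onset_time=60.0,
                             initial_pole_distance=12.0, jitter_sd=0.0,
                             n_frames=24, frame_interval=15.0)
        truth = simulate_spindle_tracks(p)
        d = truth.info["pole_distance"]
        t = truth.info["t_s"]
        # constant before onset, then d = 12 + 2/60 * (t - 60)
        assert np.allclose(d[t <= 60.0], 12.0)
        assert np.interp(180.0, t, d) == pytest.approx(16.0, abs=1e-12)

    def test_zero_velocity_keeps_distance_constant(self):
        p = SpindleSimParams(v_B=0.0, v_A=0.0, jitter_sd=0.0)
        truth = simulate_spindle_tracks(p)
        assert np.ptp(truth.info["pole_distance"]) == 0.0

    def test_sister_distance_grows_at_vB_plus_2vA(self):
        p = SpindleSimParams(v_B=2.0, v_A=0.5, jitter_sd=0.0, n_frames=20)
        truth = simulate_spindle_tracks(p)
        t = truth.info["t_s"]
        d = truth.info["sister_distance"]
        post = (t >= 60.0) & (t <= 240.0)
        slope = np.polyfit(t[post], d[post], 1)[0] * 60.0
        assert slope == pytest.approx(2.0 + 2 * 0.5, abs=1e-9)

    def test_ols_on_jittered_tracks_recovers_vB_within_3sd(self):
        # closed-form OLS slope-error oracle: distance jitter sd is
        # sqrt(2) * jitter_sd, slope se = sd / sqrt(sum (t - tbar)^2)
        p = SpindleSimParams(v_B=2.0, jitter_sd=0.05, n_frames=24, seed=11)
        truth = simulate_spindle_tracks(p)
        t = truth.info["t_s"]
        tr = truth.tracks
        poles = tr[tr["label"] == "pole"]
        d = (poles[poles["object_id"] == "pole_2"]["x_um"].to_numpy()
             - poles[poles["object_id"] == "pole_1"]["x_um"].to_numpy())
        win = (t >= 60.0) & (t <= 180.0)
        slope = np.polyfit(t[win], d[win], 1)[0] * 60.0
        tw = t[win]
        se = np.sqrt(2) * 0.05 / np.sqrt(((tw - tw.mean()) ** 2).sum()) * 60.0
        assert abs(slope - 2.0) < 3.0 * se

    def test_non_physical_params_rejected(self):
        with pytest.raises(ValueError, match="non-physical"):
            simulate_spindle_tracks(
                SpindleSimParams(initial_sister_distance=13.0,
                                 initial_pole_distance=12.0))
        with pytest.raises(ValueError):
            simulate_spindle_tracks(SpindleSimParams(v_B=-1.0))
        with pytest.raises(ValueError, match="onset"):
            simulate_spindle_tracks(SpindleSimParams(onset_time=1e6))

    def test_determinism_bit_identical(self):
        p = SpindleSimParams(seed=42)
        a = simulate_spindle_tracks(p)
        b = simulate_spindle_tracks(p)
        pd.testing.assert_frame_equal(a.tracks, b.tracks)


class TestRenderFrames:
    def _static_truth(self, x=0.0, y=0.0, n_frames=3):
        frames = np.arange(n_frames)
        tracks = pd.DataFrame({"object_id": "s", "label": "spot",
                               "frame": frames, "t_s": frames * 1.0,
                               "x_um": x, "y_um": y})
        return GroundTruth(tracks, 0.083, 1.0, {"n_frames": n_frames})

    def test_signal_conservation_without_noise(self):
        from spindleq import render_frames
        truth = self._static_truth()
        stack = render_frames(truth, RenderOptics(noise=False,
                                                  background=0.0))
        sums = stack.data.sum(axis=(1, 2))
        assert np.allclose(sums, 1000.0, rtol=1e-3)  # < 0.1% discretization
        assert np.ptp(sums) / sums.mean() < 1e-6     # constant over time

    def test_background_only_frame_mean(self):
        tracks = pd.DataFrame({"object_id": [], "label": [], "frame": [],
                               "t_s": [], "x_um": [], "y_um": []})
        truth = GroundTruth(tracks, 0.083, 1.0, {"n_frames": 2})
        from spindleq import render_frames
        stack = render_frames(truth, RenderOptics(noise=False,
                                                  background=7.0,
                                                  shape=(32, 32),
                                                  origin=(0.0, 0.0)))
        assert stack.data.mean() == pytest.approx(7.0, abs=1e-12)

    def test_undersampled_psf_rejected(self):
        from spindleq import render_frames
        with pytest.raises(ValueError, match="undersampled"):
            render_frames(self._static_truth(),
                          RenderOptics(psf_sigma=0.05))

    def test_positions_outside_fov_rejected(self):
        from spindleq import render_frames
        with pytest.raises(ValueError, match="outside"):
            render_frames(self._static_truth(x=50.0),
                          RenderOptics(shape=(32, 32), origin=(0.0, 0.0)))

    def test_bleach_factor_applied_per_frame(self):
        from spindleq import render_frames
        truth = self._static_truth(n_frames=4)
        stack = render_frames(truth, RenderOptics(noise=False,
                                                  background=0.0,
                                                  bleach_rate=0.1))
        sums = stack.data.sum(axis=(1, 2))
        expected = 1000.0 * np.exp(-0.1 * np.arange(4))
        assert np.allclose(sums, expected, rtol=1e-3)

    def test_seeded_noise_bit_identical(self):
        from spindleq import render_frames
        truth = self._static_truth()
        a = render_frames(truth, RenderOptics(seed=5))
        b = render_frames(truth, RenderOptics(seed=5))
        assert np.array_equal(a.data, b.data)


class TestPABand:
    def test_static_band_conserves_width_and_intensity(self):
        pa = PABandSimParams(v_slide=0.0, survival_30s=1.0, bleach_rate=0.0,
                             n_frames=10)
        stack, truth = simulate_pa_band(
            pa, optics=RenderOptics(noise=False, background=0.0))
        sums = stack.data.sum(axis=(1, 2))
        assert np.ptp(sums) / sums.mean() < 1e-6
        assert np.ptp(truth.info["true_widths"]) == 0.0

    def test_band_extent_grows_at_v_slide(self):
        pa = PABandSimParams(v_slide=1.0, n_frames=45)
        _, truth = simulate_pa_band(
            pa, optics=RenderOptics(noise=False, background=0.0))
        w = truth.info["true_widths"]
        t = truth.info["t_s"]
        assert np.interp(30.0, t, w) - w[0] == pytest.approx(0.5, abs=1e-12)

    def test_survival_ratio_by_direct_summation(self):
        # frame interval 0.75 s puts a frame exactly at t = 30 s
        pa = PABandSimParams(v_slide=1.0, survival_30s=0.7, bleach_rate=0.0,
                             frame_interval=0.75, n_frames=42)
        stack, _ = simulate_pa_band(
            pa, optics=RenderOptics(noise=False, background=0.0))
        ratio = stack.data[40].sum() / stack.data[0].sum()
        assert ratio == pytest.approx(0.70, abs=0.01)

    def test_band_wider_than_gap_warns_but_renders(self):
        pa = PABandSimParams(band_thickness=5.0, n_frames=5)
        with pytest.warns(UserWarning, match="wider"):
            stack, _ = simulate_pa_band(
                pa, optics=RenderOptics(noise=False, background=0.0))
        assert stack.n_frames == 5

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PABandSimParams(survival_30s=1.5).validate()
        with pytest.raises(ValueError):
            PABandSimParams(v_slide=-1.0).validate()
        with pytest.raises(ValueError):
            PABandSimParams(n_points=0).validate()


class TestComets:
    def test_zero_rates_give_empty_movie(self):
        cp = CometSimParams(nucleation_rate_astral=0.0,
                            nucleation_rate_midzone=0.0, n_frames=10)
        stack, truth = simulate_comets(
            cp, optics=RenderOptics(noise=False, background=3.0))
        assert len(truth.tracks) == 0
        counts = truth.info["region_counts"]
        assert (counts[["astral1", "astral2", "midzone", "other"]]
                .to_numpy().sum() == 0)
        assert stack.n_frames == 10
        assert stack.data.max() == pytest.approx(3.0, abs=1e-9)

    def test_nucleation_totals_match_poisson_oracle(self):
        cp = CometSimParams(nucleation_rate_astral=1.0,
                            nucleation_rate_midzone=0.5, n_frames=60,
                            seed=123)
        _, truth = simulate_comets(cp, optics=RenderOptics(noise=False))
        for region, rate in (("astral", 1.0), ("midzone", 0.5)):
            expected = rate * 60.0
            realized = truth.info["n_nucleated"][region]
            assert abs(realized - expected) < 3.0 * np.sqrt(expected)

    def test_comet_trace_slope_matches_v_comet(self):
        cp = CometSimParams(v_comet=20.0, mean_lifetime=1e6,
                            nucleation_rate_astral=0.0,
                            nucleation_rate_midzone=0.2, n_frames=20,
                            seed=3)
        _, truth = simulate_comets(cp, optics=RenderOptics(noise=False))
        one = truth.tracks[truth.tracks["object_id"]
                           == truth.tracks["object_id"].iloc[0]]
        disp = np.hypot(np.diff(one["x_um"]), np.diff(one["y_um"]))
        dt = np.diff(one["t_s"])
        assert np.allclose(disp / dt * 60.0, 20.0, atol=1e-9)

    def test_truth_labels_every_rendered_object(self):
        cp = CometSimParams(n_frames=15, seed=9)
        _, truth = simulate_comets(cp, optics=RenderOptics(noise=False))
        assert truth.tracks["region"].isin(
            ["astral1", "astral2", "midzone", "other"]).all()
        assert truth.tracks["birth_region"].isin(
            ["astral1", "astral2", "midzone"]).all()


def test_render_then_remeasure_recovers_position():
    """Truth/render consistency: noiseless spot localized within 0.05 px."""
    from spindleq import detect_spots_gaussian, render_frames

    tracks = pd.DataFrame({"object_id": "s", "label": "spot", "frame": [0],
                           "t_s": [0.0], "x_um": [1.237], "y_um": [0.981]})
    truth = GroundTruth(tracks, 0.083, 1.0, {"n_frames": 1})
    stack = render_frames(truth, RenderOptics(noise=False, background=1.0))
    dets = detect_spots_gaussian(stack.data[0], sigma0=1.5,
                                 intensity_offset=5.0)
    assert len(dets) == 1
    cx, ry = stack.um_to_px(1.237, 0.981)
    assert abs(dets[0].x_px - cx) < 0.05
    assert abs(dets[0].y_px - ry) < 0.05
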
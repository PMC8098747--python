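import numpy as np
import pytest

from spindleq.simulate import (RenderOptics, SpindleSimParams, flux_for_snr,
                               simulate_spindle_tracks)


@pytest.fixture
def clean_spindle_truth():
    """Noise-free spindle kinematics: v_B=2, onset 60 s, 12 μm spindle."""
    params = SpindleSimParams(v_B=2.0, v_A=0.5, onset_time=60.0,
                              initial_pole_distance=12.0, n_kt_pairs=2,
                              jitter_sd=0.0, n_frames=24, seed=0)
    return simulate_spindle_tracks(params)


@pytest.fixture
def noiseless_optics():
    return RenderOptics(noise=False, background=0.0)


def optics_at_snr(snr, background=10.0, psf_sigma=0.11, pixel_size=0.083,
                  seed=0):
    """Render optics whose spot peak sits at the requested SNR."""
    optics = RenderOptics(background=background, psf_sigma=psf_sigma,
                          seed=seed)
    optics.flux = flux_for_snr(snr, optics, pixel_size)
    return optics


def seeds_from(master, n):
    """Deterministic child seeds below 2**31 for a batch of simulations."""
    rng = np.random.default_rng(np.random.SeedSequence(master))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
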
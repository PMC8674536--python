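import numpy as np
import pytest

from gammarep import synthio as sio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """Four stimuli with a fixed 60 Hz peak and flat trajectories."""
    return sio.GroundTruth.random(
        [f"s{i + 1:02d}" for i in range(4)], np.random.default_rng(0),
        gamma_peak_hz=60.0, gamma_base_power=3.0, gamma_early_slope=0.0,
        gamma_late_slope=0.0, gamma_freq_shift_hz=0.0)


@pytest.fixture(scope="session")
def small_session(small_truth):
    """One 40-trial, 4-site synthetic session (4 stimuli x 10 reps)."""
    trials = sio.generate_natural_sequence(4, 10, 3, 4, seed=3)
    return sio.synthesize_recording(trials, small_truth, n_sites=4, fs=500.0,
                                    seed=1, session_gain_sd=0.0)
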
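import numpy as np
import pytest

from nfmotion import synth


@pytest.fixture(scope="session")
def clean_fs():
    """Noise-free FS recording with known pulse geometry."""
    rec, truth = synth.gen_fs_recording(
        n_steps=10, rate_hz=1.5, base_height=0.12, noise_sd=0.0, seed=1,
        pulse_duration=0.3,
    )
    return rec, truth


@pytest.fixture(scope="session")
def noisy_fs():
    rec, truth = synth.gen_fs_recording(
        n_steps=10, rate_hz=1.5, base_height=0.12, noise_sd=0.1, seed=2,
    )
    return rec, truth


@pytest.fixture(scope="session")
def clean_hps():
    rec, truth = synth.gen_hps_recording(
        n_turns=10, rate_hz=1.5, amplitude_deg=160.0, noise_sd=0.0, seed=1,
    )
    return rec, truth


@pytest.fixture(scope="session")
def lfp_session():
    from nfmotion.protocol import default_protocol

    truth = synth.LfpGroundTruth(
        beta_peak_hz=20.0,
        modulation_by_segment={"nf1_down": 1.0, "nf2_down": 0.9,
                               "nf3_down": 0.85},
    )
    session = synth.gen_lfp_session(default_protocol(), truth, seed=7)
    return session, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
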
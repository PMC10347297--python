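import numpy as np
import pytest

from gyrobeat.synthetic import SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free, jitter-free paired recording: exact ground truth."""
    cfg = SynthConfig(
        n_beats=30,
        snr_db=None,
        r_ao_jitter_ms=0.0,
        morphology_jitter=0.0,
        resp_mod_depth=0.0,
        seed=7,
    )
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def noisy_recording():
    """Default study conditions: SNR 10 dB, 3 ms R-AO jitter, 5% morphology jitter."""
    cfg = SynthConfig(n_beats=120, seed=7)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth
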
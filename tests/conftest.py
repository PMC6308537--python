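import numpy as np
import pytest

from pulsebp.synthetic import DEFAULT_COUPLING, generate_record


@pytest.fixture(scope="session")
def coupling():
    return DEFAULT_COUPLING


@pytest.fixture(scope="session")
def clean_record():
    """A zero-noise 20 s acquisition at 120/80, fs 500 Hz, with truth."""
    return generate_record(120.0, 80.0, fs=500.0, duration=20.0)


@pytest.fixture(scope="session")
def noisy_record():
    """A 20 dB SNR acquisition with drift, fs 500 Hz, with truth."""
    return generate_record(
        130.0, 85.0, fs=500.0, duration=20.0, noise_snr_db=20.0,
        drift_amp=0.1, seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
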
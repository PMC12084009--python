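import numpy as np
import pytest

from neuroei.synthetic_eeg import EEGSimSpec, generate_eeg
from neuroei.synthetic_mrs import MRSSimSpec, generate_mega_press_acquisition


@pytest.fixture(scope="session")
def clean_recording():
    """A 60 s aperiodic + alpha recording, artifact-free."""
    spec = EEGSimSpec(aperiodic_exponent=1.5, duration=60.0, seed=11)
    ts, _ = generate_eeg(spec)
    return ts


@pytest.fixture(scope="session")
def noise_free_acquisition():
    """MEGA-PRESS acquisition with zero noise (exact generative truth)."""
    return generate_mega_press_acquisition(MRSSimSpec(noise_sd=0.0, seed=5))


@pytest.fixture(scope="session")
def noisy_acquisition():
    """Acquisition at the default (visual-cortex-like, SNR ~ 20) noise."""
    return generate_mega_press_acquisition(MRSSimSpec(seed=6))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
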
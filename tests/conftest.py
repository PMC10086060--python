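import numpy as np
import pytest

from greenwave import LandscapeSpec, make_landscape


@pytest.fixture(scope="session")
def quiet_landscape():
    """Noise-free corridor: exact profiles for construction-based checks."""
    return make_landscape(LandscapeSpec(noise_sd_peakdate=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_landscape():
    """Default study landscape: 240-km corridor, 32-km reversed initial
    segment, 2-day peak-date pixel noise."""
    return make_landscape(LandscapeSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
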
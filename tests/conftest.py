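import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from vibroclust.spectra import FrequencyGrid


@pytest.fixture
def fingerprint_grid() -> FrequencyGrid:
    return FrequencyGrid(400.0, 1800.0, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
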
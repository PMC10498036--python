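import numpy as np
import pytest
from hypothesis import settings

from metabehave import SimConfig

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def clean_config() -> SimConfig:
    """Noise-free, drift-free study configuration."""
    return SimConfig(seed=0, noise_sd_frac=0.0, baseline_drift_frac_per_min=0.0)


@pytest.fixture
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
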
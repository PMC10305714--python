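import numpy as np
import pytest

from driveact.synthetic import SyntheticConfig, synthesize_recording


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_primary=24, n_secondary=8, duration_range_s=(2.06, 8.0), seed=7)


@pytest.fixture(scope="session")
def sample_recording():
    return synthesize_recording(0, 10.0, SyntheticConfig(seed=42), seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
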
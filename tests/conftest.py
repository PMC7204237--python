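import numpy as np
import pytest

from mirhp.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size synthetic study: 84 cows x 2 cow-days, default noise."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Smaller dataset for fast pipeline and IO tests."""
    return generate_dataset(GeneratorConfig(seed=7, n_cows=20, obs_per_cow=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
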
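import numpy as np
import pytest

from satrain.config import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Two-subject cohort for fast end-to-end tests."""
    return CohortConfig(n_subjects=2, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from satrain.synthetic import simulate_cohort
    return simulate_cohort(small_config)
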
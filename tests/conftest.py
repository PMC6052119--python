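import numpy as np
import pytest

from ectohrv import CohortConfig, IBISeries, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A light cohort: 4 subjects, 5-minute records."""
    return CohortConfig(n_subjects=4, duration=300.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_series(values, flags=None) -> IBISeries:
    return IBISeries(np.asarray(values, dtype=float), flags=flags)
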
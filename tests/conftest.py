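import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import menarchemr as m

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_params():
    return m.SimParams(n_individuals=3000, n_snps=60, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return m.generate_cohort(small_params)


@pytest.fixture(scope="session")
def small_pair(small_params):
    return m.generate_summary_pair(small_params)


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size cohort at the study's default conditions (shared: costly)."""
    return m.generate_cohort(m.SimParams(seed=202))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
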
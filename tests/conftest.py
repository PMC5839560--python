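import numpy as np
import pytest

from pharmcare_cea import study
from pharmcare_cea.cohort import CohortConfig
from pharmcare_cea.distributions import DistributionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20060101)


@pytest.fixture
def small_cohort_config():
    """Study-shaped cohort scaled down for fast unit tests."""
    return CohortConfig(seed=7, n_patients=40, n_complete=25)


@pytest.fixture
def lognormal_spec():
    return DistributionSpec(family="log_normal", mean=197.11, sd=130.20,
                            minimum=13.70, maximum=560.70).fit()


@pytest.fixture
def reference_cost_specs():
    return study.year_cost_specs()
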
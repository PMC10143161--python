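import numpy as np
import pytest

from lssrobust.fixtures import (DEFAULT_SIGMA_TRUE, FixtureSpec,
                                make_fixture_prior,
                                make_observed_posterior_values)
from lssrobust.mixture import build_mixture, sample_parameters
from lssrobust.simulate import SimulationConfig, filter_gfr, simulate_cohort


@pytest.fixture(scope="session")
def fixture_prior():
    """The default synthetic 50-point support prior."""
    return make_fixture_prior(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def observed_values(fixture_prior):
    """Synthetic observed posterior parameter values (n=500, fixed seed)."""
    return make_observed_posterior_values(fixture_prior, n=500, seed=11)


@pytest.fixture(scope="session")
def small_cohort(fixture_prior):
    """A filtered 60-subject cohort for estimator-level tests."""
    spec = build_mixture(fixture_prior, DEFAULT_SIGMA_TRUE)
    theta = sample_parameters(spec, 60, fixture_prior.bounds, seed=5)
    cohort = simulate_cohort(theta, SimulationConfig(n_subjects=60, seed=5))
    retained, _, _ = filter_gfr(cohort)
    return retained


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
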
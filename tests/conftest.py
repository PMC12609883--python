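import numpy as np
import pytest

from orbitmorph.synthetic_data import (
    CovariateModel,
    default_morphotype_parameters,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_params():
    return default_morphotype_parameters()


@pytest.fixture(scope="session")
def big_cohort():
    """One large cohort shared by the distribution-level checks."""
    return generate_cohort(n=100_000, seed=12345)


@pytest.fixture(scope="session")
def big_frame(big_cohort):
    return big_cohort.data


@pytest.fixture(scope="session")
def no_covariate_cohort():
    """Cohort with every covariate effect switched off."""
    cov = CovariateModel(age_width_spearman_target=0.0)
    return generate_cohort(covariates=cov, n=30_000, seed=4242)


def truncnorm_moments_quadrature(mean, sd, lo, hi):
    """Mean and variance of a range-truncated normal by numerical quadrature.

    Independent oracle for the rejection-sampling generator: integrates
    the renormalized normal density directly instead of using any
    truncated-normal distribution object.
    """
    from scipy.integrate import quad
    from scipy.stats import norm

    z = quad(lambda x: norm.pdf(x, mean, sd), lo, hi)[0]
    m1 = quad(lambda x: x * norm.pdf(x, mean, sd), lo, hi)[0] / z
    m2 = quad(lambda x: x * x * norm.pdf(x, mean, sd), lo, hi)[0] / z
    return m1, m2 - m1 * m1


@pytest.fixture(scope="session")
def quadrature_oracle():
    return truncnorm_moments_quadrature


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
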
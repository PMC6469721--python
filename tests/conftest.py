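import numpy as np
import pytest

from edgedrop import (
    DeficitPGFSpec,
    EpidemicParams,
    GeometricDegree,
    PoissonDegree,
    truncate,
)


@pytest.fixture(scope="session")
def poisson5():
    return PoissonDegree(5.0)


@pytest.fixture(scope="session")
def geometric16():
    return GeometricDegree(1.0 / 6.0)


@pytest.fixture(scope="session")
def poisson5_t15(poisson5):
    return truncate(poisson5, 15, tail_tol=1e-3)


@pytest.fixture(scope="session")
def geometric16_t50(geometric16):
    return truncate(geometric16, 50, tail_tol=1e-3)


@pytest.fixture(scope="session")
def params_dropping():
    """beta=3/2, gamma=1, omega=2: the main dropping configuration."""
    return EpidemicParams(1.5, 1.0, 2.0)


@pytest.fixture(scope="session")
def params_fig1():
    """beta=3/2, gamma=1, omega=1: the temporal-behaviour configuration."""
    return EpidemicParams(1.5, 1.0, 1.0)


@pytest.fixture(scope="session")
def spec_poisson_eps(poisson5_t15):
    """5% of the population initially infective, in degree proportions."""
    return DeficitPGFSpec(poisson5_t15, 0.05 * poisson5_t15.pmf)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
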
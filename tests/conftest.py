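import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dielbfc import NIGPrior, build_basis, make_design

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_design():
    """3 kinetics x 9 time points (duplicated dawn point), 12:12 L/D."""
    return make_design()


@pytest.fixture(scope="session")
def default_basis(default_design):
    return build_basis(default_design)


@pytest.fixture(scope="session")
def default_prior():
    return NIGPrior()


@pytest.fixture(scope="session")
def flat_prior():
    """Essentially non-informative coefficient prior for analytic checks."""
    return NIGPrior(m0=0.0, v0=1e9, a0=0.001, b0=0.001)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
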
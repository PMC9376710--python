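import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sir_net():
    from opetri import fixtures as fx

    return fx.sir()


@pytest.fixture
def p_inf():
    from opetri import fixtures as fx

    return fx.p_infectious()


@pytest.fixture
def sviivr():
    """(wiring diagram, open components) of the vaccination composite."""
    from opetri import fixtures as fx

    return fx.uwd_fig2a(), fx.sviivr_components()
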
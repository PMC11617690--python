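import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import copot as cp

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def printed_fit():
    """The reference GP tail fit: d0 = 4.84 m, sigma = 2.60, gamma = -0.493."""
    return cp.GPDParams(threshold_u=-4.84, scale_sigma=2.60, shape_gamma=-0.493)


@pytest.fixture
def default_spec():
    return cp.ScenarioSpec()


@pytest.fixture
def gumbel_ref():
    """Gumbel copula at the reference dependence level (tau ~ 0.145)."""
    return cp.CopulaModel("gumbel", 1.169)
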
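import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitoswell as ms

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def consts():
    return ms.PopulationConstants()


@pytest.fixture
def liver_params():
    """Rat-liver reference fit at 50 uM Ca2+ (all four parameters free)."""
    return ms.SwellingParameters(a=0.2544, b=0.0118, k=0.7360, tau=16.2803)


@pytest.fixture
def table50_params():
    """Fixed-b titration fit at 50 uM Ca2+."""
    return ms.SwellingParameters(a=0.1882, b=0.021, k=0.7370, tau=18.0899)


@pytest.fixture
def grid():
    return ms.default_grid()


@pytest.fixture
def noiseless_liver_curve(liver_params):
    return ms.generate_curve(liver_params)
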
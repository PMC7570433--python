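import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fractumor.model import HEADLINE_PARAMS

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def headline():
    """Parameter set of the headline simulations (chaotic regime)."""
    return HEADLINE_PARAMS


@pytest.fixture()
def relax_field():
    """Linear relaxation vector field dy/dt = -y."""
    return lambda t, y: -np.asarray(y)
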
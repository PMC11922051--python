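import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from papeors import make_transducer_ir

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 1e9


@pytest.fixture(scope="session")
def ir_75mhz():
    """The study transducer: 7.5 MHz center, 60% fractional bandwidth."""
    return make_transducer_ir(7.5e6, 0.6, FS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250922)
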
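import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epireg.datatypes import Panel

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_panel() -> Panel:
    return Panel(("LINE_A", "LINE_B", "LINE_C", "LINE_D", "LINE_E", "LINE_F"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def warm_fit_kernel():
    """Compile the sigmoid-fit kernel once for the whole session."""
    from epireg import _sigfit

    M = np.linspace(0, 100, 8)
    E = np.linspace(50, 5, 8)
    _sigfit.fit_pairs(M[None], E[None])
    return True
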
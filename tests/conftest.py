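import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from myomri.phantom import build_phantom, mouse_hindlimb_spec


@pytest.fixture(scope="session")
def gt_wt():
    """Full-size wild-type phantom (muscle FF 0.09 %, T2 18.8 ms)."""
    return build_phantom(mouse_hindlimb_spec("WT"))


@pytest.fixture(scope="session")
def gt_tg():
    """Full-size transgenic phantom (muscle FF 0.19 %, T2 19.8 ms)."""
    return build_phantom(mouse_hindlimb_spec("Tg"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
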
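import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from swdsim.design import build_design


@pytest.fixture(scope="session")
def paper_design():
    """The 18-cluster, 13-period, 3-month-period motivating layout."""
    return build_design(18, 13, 2, 2, 3.0)


@pytest.fixture(scope="session")
def small_design():
    """6 clusters x 5 periods: fast enough for every model."""
    return build_design(6, 5, 1, 2, 3.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210316)
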
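import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from texcue.mechanisms import load_isoluminance_table
from texcue.stimulus import make_ladder

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def observer_ks() -> list[float]:
    """The seven measured L:M luminance weights from the isoluminance table."""
    return load_isoluminance_table()["k"].tolist()


@pytest.fixture(scope="session")
def default_ladder():
    """Symmetric 8-level ladder used as the study-scale design in tests."""
    return make_ladder(0.1, 0.32, 0.1, 0.32)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
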
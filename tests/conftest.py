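import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def grid8():
    """Default 8-s / 4-s epoch grid over a 10-minute record."""
    from neoseize import EpochGrid

    return EpochGrid(record_duration_s=600.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20241001)
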
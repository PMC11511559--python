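import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def chain_montage():
    """A 3-electrode chain A-B-C with hand-written neighbor sets."""
    from bcikit.eeg_core import Montage

    return Montage(
        positions={"A": (0.0, 0.0), "B": (1.0, 0.0), "C": (2.0, 0.0)},
        small_neighbors={
            "A": frozenset({"B"}),
            "B": frozenset({"A", "C"}),
            "C": frozenset({"B"}),
        },
        large_neighbors={
            "A": frozenset({"C"}),
            "B": frozenset({"A", "C"}),
            "C": frozenset({"A"}),
        },
    )


@pytest.fixture(scope="session")
def motor_montage():
    from bcikit.eeg_core import motor_strip_montage

    return motor_strip_montage()
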
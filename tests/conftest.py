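import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from probmcda import Criterion, Direction, depression_case

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def unit_criteria() -> list[Criterion]:
    """Two maximized + one minimized probability criterion with 0-1 anchors."""
    return [
        Criterion("benefit_1", Direction.MAXIMIZE, 0.0, 1.0),
        Criterion("benefit_2", Direction.MAXIMIZE, 0.0, 1.0),
        Criterion("risk", Direction.MINIMIZE, 1.0, 0.0),
    ]


@pytest.fixture(scope="session")
def patient_case():
    return depression_case("patients")


@pytest.fixture(scope="session")
def expert_case():
    return depression_case("experts")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150)
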
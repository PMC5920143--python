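import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import amputebias as ab

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def school_cohort() -> ab.StudyTable:
    """One fixed complete school cohort (default spec, seed 11)."""
    return ab.generate_school_cohort(ab.SchoolCohortSpec(seed=11))


@pytest.fixture(scope="session")
def prison_cohort():
    """One fixed complete prison cohort plus its preset dropout mask."""
    return ab.generate_prison_cohort(ab.PrisonCohortSpec(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
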
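import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from painintervals import Cohort, PainInterval, PatientRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def patient3_intervals():
    """Non-overlapping pre/post intervals from the worked example."""
    return PainInterval(2.1, 3.7), PainInterval(3.8, 5.2)


@pytest.fixture
def patient1_points():
    """Traditional point estimates: pre 7.2, post 3.6 (effect -3.6)."""
    return PainInterval(7.2, 7.2), PainInterval(3.6, 3.6)


@pytest.fixture
def two_patient_cohort():
    """Worked-example cohort: P1 point estimates, P3 intervals."""
    return Cohort(
        (
            PatientRecord("P1", PainInterval(7.2, 7.2), PainInterval(3.6, 3.6)),
            PatientRecord("P3", PainInterval(2.1, 3.7), PainInterval(3.8, 5.2)),
        )
    )


@pytest.fixture
def point_cohort():
    """Five identical point-estimate patients, effect exactly -3.6."""
    records = tuple(
        PatientRecord(f"P{i}", PainInterval(7.2, 7.2), PainInterval(3.6, 3.6))
        for i in range(5)
    )
    return Cohort(records)


def random_interval(rng: np.random.Generator, scale=(0.0, 10.0)) -> PainInterval:
    lo = rng.uniform(scale[0], scale[1])
    hi = rng.uniform(lo, scale[1])
    return PainInterval(lo, hi)
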
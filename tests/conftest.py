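import numpy as np
import pytest

from namdsim import (
    DEFAULT_PARAMETERS,
    OCEAN_PROFILE,
    InjectionSchedule,
    PatientBaseline,
    generate_cohort,
)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMETERS


@pytest.fixture
def patient():
    return PatientBaseline(
        patient_id="REF", age=77.0, g0=52.1, pretreatment="naive", delay=0.0, obs_end=730.5
    )


@pytest.fixture
def q8w_schedule():
    from namdsim import make_3l_q8w_schedule

    return make_3l_q8w_schedule(547.875)


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient cohort shared by estimation/scenario unit tests."""
    rng = np.random.default_rng(42)
    return generate_cohort(OCEAN_PROFILE.with_(n_patients=200), rng)


@pytest.fixture
def empty_schedule():
    return InjectionSchedule()
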
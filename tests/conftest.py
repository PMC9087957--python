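from datetime import date, datetime

import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from empirx import example_kb
from empirx.patient_data import Observation, PatientRecord

NOW = datetime(2017, 3, 1, 10, 0)


@pytest.fixture(scope="session")
def kb():
    return example_kb()


@pytest.fixture()
def now():
    return NOW


def make_patient(**overrides) -> PatientRecord:
    """A well-formed adult inpatient; override any field."""
    base = dict(
        patient_id="P1",
        birth_date=date(1960, 6, 15),
        sex="female",
        ward="internal_medicine",
        admission_start=datetime(2017, 2, 25, 9, 0),
        admission_end=datetime(2017, 3, 6, 12, 0),
        weight_kg=70.0,
        height_cm=168.0,
        pregnant=False,
        observations=[
            Observation(kind="egfr", value=80.0, observed_at=datetime(2017, 2, 27, 8, 0)),
            Observation(kind="neutrophils", value=4.2, observed_at=datetime(2017, 2, 27, 8, 0)),
        ],
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture()
def patient():
    return make_patient()
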
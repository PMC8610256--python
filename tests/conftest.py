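import pandas as pd
import pytest

from parrisk.ehr_features import (
    Dispensing,
    LabResult,
    PatientAdmission,
    bundled_comorbidity_map,
)
from parrisk.score_model import bundled_score_definition
from parrisk.synthetic_cohort import CohortConfig, generate_cohort, write_cohort

T0 = pd.Timestamp("2021-01-01 08:00")


def make_admission(
    patient_id="P1",
    age=75,
    sex="F",
    admission_ts=T0,
    los_hours=120,
    residency="Swiss",
    disposition="home",
    diagnoses=(),
    dispensings=(),
    dispensing_available=True,
    labs=(),
    prior_admissions=(),
):
    """Hand-built admission with sensible defaults for single-rule tests."""
    return PatientAdmission(
        patient_id=patient_id,
        age=age,
        sex=sex,
        admission_ts=admission_ts,
        discharge_ts=admission_ts + pd.Timedelta(hours=los_hours),
        residency=residency,
        disposition=disposition,
        diagnoses=list(diagnoses),
        dispensings=[Dispensing(*d) for d in dispensings],
        dispensing_available=dispensing_available,
        labs=[LabResult(*lab) for lab in labs],
        prior_admissions=list(prior_admissions),
    )


@pytest.fixture(scope="session")
def score_def():
    return bundled_score_definition()


@pytest.fixture(scope="session")
def cmap():
    return bundled_comorbidity_map()


@pytest.fixture(scope="session")
def synthetic_cohort():
    """A moderate generated cohort: tables plus its configuration."""
    cfg = CohortConfig(n_patients=2000, seed=11)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, synthetic_cohort):
    """The same cohort written out as the CSV tables the pipeline reads."""
    _, tables = synthetic_cohort
    d = tmp_path_factory.mktemp("cohort")
    write_cohort(tables, d)
    return d
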
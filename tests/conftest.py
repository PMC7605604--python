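"""Shared fixtures: tiny hand-built cohorts and seeded generated panels."""

from __future__ import annotations

import pytest

from t2dss.ehr_core import cohort_from_records
from t2dss.synthetic_cohort import CohortConfig, generate_cohort

AS_OF = "2019-12-31"


def make_patient(pid="P1", gp="G1", birth="1960-05-01", **kw):
    base = dict(
        patient_id=pid, gp_id=gp, birth_date=birth, sex="F",
        risk_flags=frozenset(), event_flags=frozenset(),
        enrolled=False, consent=True,
    )
    base.update(kw)
    return base


def make_cohort(patients=(), observations=(), conditions=(), prescriptions=(),
                as_of=AS_OF):
    return cohort_from_records(patients, observations, conditions, prescriptions,
                               as_of=as_of)


def obs(pid, code, value, date):
    return dict(patient_id=pid, code=code, value=value, date=date)


def enrolled_t2d(pid="P1", gp="G1", onset="2015-01-01", **kw):
    """(patient dict, T2D condition dict) for an enrolled diabetic."""
    patient = make_patient(pid, gp, enrolled=True, **kw)
    cond = dict(patient_id=pid, condition="T2D", onset_date=onset)
    return patient, cond


@pytest.fixture(scope="session")
def gen_cohort_small():
    """Mixed 400-patient panel, default study conditions."""
    return generate_cohort(CohortConfig(n_patients=400, n_gps=4, seed=7))


@pytest.fixture(scope="session")
def gen_cohort_t2d():
    """Mostly-diabetic panel used for indicator and label tests."""
    return generate_cohort(
        CohortConfig(n_patients=250, n_gps=3, t2d_prevalence=0.9, seed=13)
    )


@pytest.fixture(scope="session")
def gen_cohort_5000():
    """Large panel for marginal-calibration checks."""
    return generate_cohort(CohortConfig(n_patients=5000, n_gps=10, seed=42))
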
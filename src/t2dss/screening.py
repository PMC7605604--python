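"""Screening of potentially diabetic subjects.

Screening relies on the fasting plasma glucose (FPG) test.  All subjects
aged 45 or over are screened; under-45 subjects are screened when their
latest BMI exceeds 25 kg/m2 *and* at least one risk condition holds
(recorded lifestyle/history flags, or conditions derived from the record:
arterial hypertension >= 140/90 mmHg or antihypertensive therapy in act,
HDL < 35 mg/dl and/or triglycerides > 250 mg/dl, HbA1c 42-48 mmol/mol).

Glycemic classification uses the latest recorded values with a fixed
precedence:

=========  ==========================================
DIABETES   FPG >= 126 mg/dl or 2h-OGTT >= 200 mg/dl
IGT        2h-OGTT 140-199 mg/dl
IFG        FPG 100-125 mg/dl
HBA1C_RISK HbA1c 42-48 mmol/mol (IFCC assay)
NORMAL     some glycemic value present, none of the above
UNKNOWN    no glycemic observation on record
=========  ==========================================

Non-diabetic subjects are re-screened every 3 years, yearly (by default)
when dysglycemic; a diabetic classification exits screening into the
new-diagnosis flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ehr_core import WINDOW_DAYS, Cohort, age_years, latest_value

__all__ = [
    "ScreeningResult",
    "screening_eligibility",
    "classify_glycemia",
    "next_screening_due",
    "screen_cohort",
    "SCREENING_START_AGE",
    "BMI_GATE",
    "FPG_DIABETES",
    "IFG_RANGE",
    "IGT_RANGE",
    "HBA1C_RISK_BAND_MMOLMOL",
]

SCREENING_START_AGE = 45
BMI_GATE = 25.0  # strict >
FPG_DIABETES = 126.0  # "< 126 is non-diagnostic", so 126 is diagnostic
OGTT_DIABETES = 200.0
IFG_RANGE = (100.0, 125.0)
IGT_RANGE = (140.0, 199.0)
HBA1C_RISK_BAND_MMOLMOL = (42.0, 48.0)
HYPERTENSION_AP = (140.0, 90.0)
LOW_HDL = 35.0  # strict <
HIGH_TRIG = 250.0  # strict >


@dataclass(frozen=True)
class ScreeningResult:
    patient_id: str
    eligible: bool
    eligibility_reasons: tuple[str, ...]
    glycemic_class: str  # NORMAL | IFG | IGT | HBA1C_RISK | DIABETES | UNKNOWN
    next_screen_due: pd.Timestamp | None = None


def _patient_row(cohort: Cohort, patient_id: str):
    rows = cohort.patients[cohort.patients["patient_id"] == patient_id]
    if rows.empty:
        raise KeyError(f"unknown patient {patient_id!r}")
    return rows.iloc[0]


def screening_eligibility(
    patient_id: str, cohort: Cohort
) -> tuple[bool, tuple[str, ...]]:
    """Whether the subject should receive an FPG screening test, with reasons."""
    row = _patient_row(cohort, patient_id)
    if pd.isna(row["birth_date"]):
        raise ValueError(f"patient {patient_id!r} has no birth_date")
    age = age_years(row["birth_date"], cohort.as_of)
    if age >= SCREENING_START_AGE:
        return True, (f"AGE_GE_{SCREENING_START_AGE}",)

    bmi = latest_value(cohort, patient_id, "BMI_KGM2")
    if bmi is None or bmi <= BMI_GATE:
        return False, ()

    reasons = [f for f in sorted(row["risk_flags"])]

    ap_sys = latest_value(cohort, patient_id, "AP_SYS_MMHG")
    ap_dia = latest_value(cohort, patient_id, "AP_DIA_MMHG")
    rx = cohort.prescriptions
    on_antihyp = not rx[
        (rx["patient_id"] == patient_id)
        & (rx["drug_class"] == "ANTIHYPERTENSIVE")
        & ((cohort.as_of - rx["date"]).dt.days <= WINDOW_DAYS)
        & (rx["date"] <= cohort.as_of)
    ].empty
    if (
        (ap_sys is not None and ap_sys >= HYPERTENSION_AP[0])
        or (ap_dia is not None and ap_dia >= HYPERTENSION_AP[1])
        or on_antihyp
    ):
        reasons.append("HYPERTENSION_DERIVED")

    hdl = latest_value(cohort, patient_id, "HDL_MGDL")
    trig = latest_value(cohort, patient_id, "TRIG_MGDL")
    if (hdl is not None and hdl < LOW_HDL) or (trig is not None and trig > HIGH_TRIG):
        reasons.append("DYSLIPIDEMIA_DERIVED")

    mmol = latest_value(cohort, patient_id, "HBA1C_MMOLMOL")
    if mmol is not None and HBA1C_RISK_BAND_MMOLMOL[0] <= mmol <= HBA1C_RISK_BAND_MMOLMOL[1]:
        reasons.append("HBA1C_RISK_BAND")

    if reasons:
        return True, tuple(["BMI_GT_25"] + reasons)
    return False, ()


def classify_glycemia(patient_id: str, cohort: Cohort) -> str:
    """Glycemic class from the latest FPG, 2h-OGTT and HbA1c (mmol/mol) values."""
    fpg = latest_value(cohort, patient_id, "FPG_MGDL")
    ogtt = latest_value(cohort, patient_id, "OGTT2H_MGDL")
    mmol = latest_value(cohort, patient_id, "HBA1C_MMOLMOL")

    if (fpg is not None and fpg >= FPG_DIABETES) or (
        ogtt is not None and ogtt >= OGTT_DIABETES
    ):
        return "DIABETES"
    if ogtt is not None and IGT_RANGE[0] <= ogtt <= IGT_RANGE[1]:
        return "IGT"
    if fpg is not None and IFG_RANGE[0] <= fpg <= IFG_RANGE[1]:
        return "IFG"
    if mmol is not None and HBA1C_RISK_BAND_MMOLMOL[0] <= mmol <= HBA1C_RISK_BAND_MMOLMOL[1]:
        return "HBA1C_RISK"
    if fpg is not None or ogtt is not None or mmol is not None:
        return "NORMAL"
    return "UNKNOWN"


def next_screening_due(
    eligible: bool,
    glycemic_class: str,
    as_of,
    *,
    dysglycemia_interval_years: int = 1,
) -> pd.Timestamp | None:
    """Date of the next screening test.

    Re-screening is at least every 3 years; dysglycemic subjects (IFG, IGT,
    HbA1c risk band) are re-tested more frequently — yearly by default.
    A DIABETES classification exits screening (new-diagnosis flow); subjects
    never tested (UNKNOWN) and eligible are due immediately.
    """
    as_of = pd.Timestamp(as_of)
    if glycemic_class == "DIABETES":
        return None
    if glycemic_class in {"IFG", "IGT", "HBA1C_RISK"}:
        return as_of + pd.DateOffset(years=dysglycemia_interval_years)
    if glycemic_class == "NORMAL":
        return as_of + pd.DateOffset(years=3)
    return as_of if eligible else None


def screen_cohort(cohort: Cohort, **kwargs) -> list[ScreeningResult]:
    """Screening results for every non-T2D patient in the cohort.

    Batch equivalent of :func:`screening_eligibility` +
    :func:`classify_glycemia`, computed from grouped latest-value tables so
    screening a panel is linear in the table sizes."""
    from .ehr_core import latest_per_patient

    t2d = cohort.has_condition("T2D")
    as_of = cohort.as_of
    latest = {
        code: latest_per_patient(cohort, code)
        for code in ("BMI_KGM2", "AP_SYS_MMHG", "AP_DIA_MMHG", "HDL_MGDL",
                     "TRIG_MGDL", "HBA1C_MMOLMOL", "FPG_MGDL", "OGTT2H_MGDL")
    }
    rx = cohort.prescriptions
    on_antihyp = set(
        rx.loc[(rx["drug_class"] == "ANTIHYPERTENSIVE")
               & (rx["date"] <= as_of)
               & ((as_of - rx["date"]).dt.days <= WINDOW_DAYS), "patient_id"]
    )

    def get(code, pid):
        s = latest[code]
        return float(s[pid]) if pid in s.index else None

    out = []
    for _, row in cohort.patients.iterrows():
        pid = row["patient_id"]
        if pid in t2d:
            continue
        if pd.isna(row["birth_date"]):
            raise ValueError(f"patient {pid!r} has no birth_date")
        age = age_years(row["birth_date"], as_of)

        if age >= SCREENING_START_AGE:
            eligible, reasons = True, (f"AGE_GE_{SCREENING_START_AGE}",)
        else:
            bmi = get("BMI_KGM2", pid)
            if bmi is None or bmi <= BMI_GATE:
                eligible, reasons = False, ()
            else:
                r = sorted(row["risk_flags"])
                ap_sys, ap_dia = get("AP_SYS_MMHG", pid), get("AP_DIA_MMHG", pid)
                if ((ap_sys is not None and ap_sys >= HYPERTENSION_AP[0])
                        or (ap_dia is not None and ap_dia >= HYPERTENSION_AP[1])
                        or pid in on_antihyp):
                    r.append("HYPERTENSION_DERIVED")
                hdl, trig = get("HDL_MGDL", pid), get("TRIG_MGDL", pid)
                if (hdl is not None and hdl < LOW_HDL) or \
                        (trig is not None and trig > HIGH_TRIG):
                    r.append("DYSLIPIDEMIA_DERIVED")
                mmol = get("HBA1C_MMOLMOL", pid)
                if mmol is not None and \
                        HBA1C_RISK_BAND_MMOLMOL[0] <= mmol <= HBA1C_RISK_BAND_MMOLMOL[1]:
                    r.append("HBA1C_RISK_BAND")
                eligible, reasons = (True, tuple(["BMI_GT_25"] + r)) if r else (False, ())

        fpg, ogtt, mmol = get("FPG_MGDL", pid), get("OGTT2H_MGDL", pid), \
            get("HBA1C_MMOLMOL", pid)
        if (fpg is not None and fpg >= FPG_DIABETES) or \
                (ogtt is not None and ogtt >= OGTT_DIABETES):
            klass = "DIABETES"
        elif ogtt is not None and IGT_RANGE[0] <= ogtt <= IGT_RANGE[1]:
            klass = "IGT"
        elif fpg is not None and IFG_RANGE[0] <= fpg <= IFG_RANGE[1]:
            klass = "IFG"
        elif mmol is not None and \
                HBA1C_RISK_BAND_MMOLMOL[0] <= mmol <= HBA1C_RISK_BAND_MMOLMOL[1]:
            klass = "HBA1C_RISK"
        elif fpg is not None or ogtt is not None or mmol is not None:
            klass = "NORMAL"
        else:
            klass = "UNKNOWN"

        due = next_screening_due(eligible, klass, as_of, **kwargs)
        out.append(ScreeningResult(pid, eligible, reasons, klass, due))
    return out
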
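"""Automatic enrollment proposals for the T2D integrated-management program.

T2D patients without major uncontrolled complications are proposed for
automatic enrollment.  A T2D patient is excluded when any of the
following holds at the evaluation date:

* a major complication is on record (coronary heart disease, ictus,
  peripheral arterial disease, retinopathy);
* uncompensated diabetes — any HbA1c observation above 8 % within the
  last year (existence, not only the latest value);
* an insulin prescription within the last year.

Patients without a T2D condition code but with ongoing antidiabetic
therapy or repeated glycemic checks are flagged as *potential* T2D —
an advisory suggestion only; the final decision always rests with the GP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import ehr_core
from .ehr_core import (
    ANTIDIABETIC_NON_INSULIN,
    EXCLUSION_CONDITIONS,
    GLYCEMIC_CODES,
    WINDOW_DAYS,
    Cohort,
    in_window,
)

__all__ = ["EnrollmentDecision", "propose_enrollment", "UNCOMPENSATED_HBA1C_PCT"]

#: HbA1c (%) above which diabetes counts as uncompensated (strict >).
UNCOMPENSATED_HBA1C_PCT = 8.0

_COMPLICATION_REASON = {
    "CHD": "COMPLICATION_CHD",
    "ICTUS": "COMPLICATION_ICTUS",
    "PERIPHERAL_ARTERIAL_DISEASE": "COMPLICATION_PAD",
    "RETINOPATHY": "COMPLICATION_RETINOPATHY",
}


@dataclass(frozen=True)
class EnrollmentDecision:
    patient_id: str
    action: str  # ENROLL | EXCLUDE | SUGGEST_ADD_POTENTIAL
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.action == "EXCLUDE" and not self.reasons:
            raise ValueError("EXCLUDE requires at least one reason")
        if self.action == "ENROLL" and self.reasons:
            raise ValueError("ENROLL must carry no reasons")


def propose_enrollment(
    cohort: Cohort,
    *,
    min_glycemic_checks: int = 2,
    window_days: int = WINDOW_DAYS,
) -> list[EnrollmentDecision]:
    """One decision per T2D patient (ENROLL or EXCLUDE with reasons) plus
    advisory SUGGEST_ADD_POTENTIAL decisions for likely-undiagnosed patients.

    ``min_glycemic_checks`` is the number of in-window glycemic observations
    (fasting glucose, OGTT, HbA1c) that makes a non-T2D patient "potential".
    """
    as_of = cohort.as_of
    t2d = cohort.has_condition("T2D")

    cond = cohort.conditions
    complicated: dict[str, list[str]] = {}
    m = cond["condition"].isin(EXCLUSION_CONDITIONS) & (cond["onset_date"] <= as_of)
    for pid, code in zip(cond.loc[m, "patient_id"], cond.loc[m, "condition"]):
        complicated.setdefault(pid, []).append(_COMPLICATION_REASON[code])

    obs = cohort.observations
    hot = (
        (obs["code"] == "HBA1C_PCT")
        & (obs["value"] > UNCOMPENSATED_HBA1C_PCT)
        & in_window(obs["date"], as_of, window_days)
    )
    uncompensated = set(obs.loc[hot, "patient_id"])

    rx = cohort.prescriptions
    rx_win = rx[in_window(rx["date"], as_of, window_days)]
    on_insulin = set(rx_win.loc[rx_win["drug_class"] == "INSULIN", "patient_id"])
    on_oral = set(
        rx_win.loc[rx_win["drug_class"].isin(ANTIDIABETIC_NON_INSULIN), "patient_id"]
    )

    gly = obs[obs["code"].isin(GLYCEMIC_CODES) & in_window(obs["date"], as_of, window_days)]
    gly_counts = gly.groupby("patient_id").size()

    decisions: list[EnrollmentDecision] = []
    for pid in cohort.patients["patient_id"]:
        if pid in t2d:
            reasons: list[str] = list(dict.fromkeys(complicated.get(pid, [])))
            if pid in uncompensated:
                reasons.append("UNCOMPENSATED_HBA1C")
            if pid in on_insulin:
                reasons.append("INSULIN_LAST_YEAR")
            if reasons:
                decisions.append(EnrollmentDecision(pid, "EXCLUDE", tuple(reasons)))
            else:
                decisions.append(EnrollmentDecision(pid, "ENROLL"))
        else:
            reasons = []
            if pid in on_oral:
                reasons.append("POTENTIAL_BY_THERAPY")
            if int(gly_counts.get(pid, 0)) >= min_glycemic_checks:
                reasons.append("POTENTIAL_BY_CHECKS")
            if reasons:
                decisions.append(
                    EnrollmentDecision(pid, "SUGGEST_ADD_POTENTIAL", tuple(reasons))
                )
    return decisions
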
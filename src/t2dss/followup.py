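"""Follow-up routing for enrolled T2D patients.

Each patient is assigned one follow-up phase:

* ``SCREENING`` — no T2D condition on record;
* ``NEW_DIAGNOSIS`` — T2D onset within the new-diagnosis horizon
  (90 days by default);
* ``A`` — T2D without complications: quarterly GP visits (weight, BMI,
  waist, blood pressure), annual lab panel, fundus oculi every 2 years;
* ``B`` — stabilized complications, insulin therapy, or inadequate
  control (HbA1c > 8 % in the last year): follow-up A activities plus a
  six-monthly diabetes-center review.

Additionally every T2D patient carries an annual diabetes-center
screening action (follow-up "C").  Specialist referral triggers are
checked separately: acute events (foot ulcer, severe hypoglycemia,
pregnancy, metabolic instability) demand an *urgent* referral, while
repeated fasting glucose above 180 mg/dl, two consecutive HbA1c above
6.5 %, or a newly recorded complication warrant a *programmable* one.

Diabetes-center visits have no dedicated observation code in the flat
schema; a recorded ECG (``ECG_DONE``) is used as the marker of the most
recent center review — a reconstruction, since the center panel includes
an ECG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ehr_core import (
    EXCLUSION_CONDITIONS,
    WINDOW_DAYS,
    Cohort,
    in_window,
)
from .enrollment import UNCOMPENSATED_HBA1C_PCT, EnrollmentDecision

__all__ = [
    "FollowUpAssignment",
    "assign_phase",
    "phases_for",
    "due_actions",
    "referral_check",
    "route_cohort",
    "PHASES",
    "NEW_DIAGNOSIS_DAYS",
    "REFERRAL_FPG",
]

PHASES = ("SCREENING", "NEW_DIAGNOSIS", "A", "B", "C_ANNUAL")

NEW_DIAGNOSIS_DAYS = 90
REFERRAL_FPG = 180.0  # strict >
REFERRAL_HBA1C = 6.5  # strict >, two most recent determinations

QUARTERLY_MARKERS = ("AP_SYS_MMHG", "AP_DIA_MMHG", "BMI_KGM2", "WAIST_CM", "WEIGHT_KG")
ANNUAL_LAB_MARKERS = ("HBA1C_PCT", "HBA1C_MMOLMOL")
CENTER_MARKERS = ("ECG_DONE",)


@dataclass(frozen=True)
class FollowUpAssignment:
    patient_id: str
    phase: str
    due_actions: tuple[tuple[str, pd.Timestamp], ...] = ()
    referral: str = "NONE"  # NONE | PROGRAMMABLE | URGENT
    referral_reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.referral == "URGENT" and not self.referral_reasons:
            raise ValueError("URGENT referral requires reasons")


def _patient_obs(cohort: Cohort, patient_id: str) -> pd.DataFrame:
    o = cohort.observations
    return o[(o["patient_id"] == patient_id) & (o["date"] <= cohort.as_of)]


def _t2d_onset(cohort: Cohort, patient_id: str):
    c = cohort.conditions
    m = (c["patient_id"] == patient_id) & (c["condition"] == "T2D")
    if not m.any():
        return None
    return c.loc[m, "onset_date"].min()


def _inadequate_control(cohort: Cohort, patient_id: str) -> tuple[bool, bool]:
    """(insulin in window, HbA1c > 8 in window)."""
    rx = cohort.prescriptions
    insulin = not rx[
        (rx["patient_id"] == patient_id)
        & (rx["drug_class"] == "INSULIN")
        & in_window(rx["date"], cohort.as_of, WINDOW_DAYS)
    ].empty
    o = _patient_obs(cohort, patient_id)
    hot = not o[
        (o["code"] == "HBA1C_PCT")
        & (o["value"] > UNCOMPENSATED_HBA1C_PCT)
        & in_window(o["date"], cohort.as_of, WINDOW_DAYS)
    ].empty
    return insulin, hot


def assign_phase(
    patient_id: str,
    cohort: Cohort,
    enrollment: EnrollmentDecision | None = None,
    screening=None,
    *,
    new_diagnosis_days: int = NEW_DIAGNOSIS_DAYS,
) -> str:
    """Follow-up phase for one patient at ``cohort.as_of``."""
    onset = _t2d_onset(cohort, patient_id)
    row = cohort.patients[cohort.patients["patient_id"] == patient_id]
    if row.empty:
        raise KeyError(f"unknown patient {patient_id!r}")
    if onset is None:
        if bool(row.iloc[0]["enrolled"]):
            raise ValueError(
                f"patient {patient_id!r} is flagged enrolled but has no T2D condition"
            )
        return "SCREENING"
    if (cohort.as_of - onset).days <= new_diagnosis_days:
        return "NEW_DIAGNOSIS"
    c = cohort.conditions
    complicated = not c[
        (c["patient_id"] == patient_id)
        & c["condition"].isin(EXCLUSION_CONDITIONS)
        & (c["onset_date"] <= cohort.as_of)
    ].empty
    insulin, hot = _inadequate_control(cohort, patient_id)
    return "B" if (complicated or insulin or hot) else "A"


def phases_for(
    cohort: Cohort,
    pids=None,
    *,
    new_diagnosis_days: int = NEW_DIAGNOSIS_DAYS,
) -> pd.Series:
    """Vectorized phase assignment for many patients at once (same rules as
    :func:`assign_phase`)."""
    p = cohort.patients
    if pids is None:
        pids = list(p["patient_id"])
    as_of = cohort.as_of

    c = cohort.conditions
    t2d = c[(c["condition"] == "T2D") & (c["onset_date"] <= as_of)]
    onset = t2d.groupby("patient_id")["onset_date"].min()
    complicated = set(
        c.loc[
            c["condition"].isin(EXCLUSION_CONDITIONS) & (c["onset_date"] <= as_of),
            "patient_id",
        ]
    )
    rx = cohort.prescriptions
    insulin = set(
        rx.loc[
            (rx["drug_class"] == "INSULIN") & in_window(rx["date"], as_of, WINDOW_DAYS),
            "patient_id",
        ]
    )
    o = cohort.observations
    hot = set(
        o.loc[
            (o["code"] == "HBA1C_PCT")
            & (o["value"] > UNCOMPENSATED_HBA1C_PCT)
            & in_window(o["date"], as_of, WINDOW_DAYS),
            "patient_id",
        ]
    )
    enrolled = dict(zip(p["patient_id"], p["enrolled"]))

    out = {}
    for pid in pids:
        if pid not in onset.index:
            if enrolled.get(pid, False):
                raise ValueError(
                    f"patient {pid!r} is flagged enrolled but has no T2D condition"
                )
            out[pid] = "SCREENING"
        elif (as_of - onset[pid]).days <= new_diagnosis_days:
            out[pid] = "NEW_DIAGNOSIS"
        elif pid in complicated or pid in insulin or pid in hot:
            out[pid] = "B"
        else:
            out[pid] = "A"
    return pd.Series(out, name="phase", dtype=object).loc[pids]


def _last_marker(cohort: Cohort, patient_id: str, codes) -> pd.Timestamp | None:
    o = _patient_obs(cohort, patient_id)
    dates = o.loc[o["code"].isin(codes), "date"]
    return None if dates.empty else dates.max()


def due_actions(
    patient_id: str, cohort: Cohort, phase: str
) -> tuple[tuple[str, pd.Timestamp], ...]:
    """Scheduled actions with due dates (last marker + period; due immediately
    when never recorded).  Due dates before ``as_of`` mean the action is
    overdue."""
    if phase == "SCREENING":
        return ()
    as_of = cohort.as_of

    def due(codes, days) -> pd.Timestamp:
        last = _last_marker(cohort, patient_id, codes)
        return as_of if last is None else last + pd.Timedelta(days=days)

    actions = [
        ("QUARTERLY_VISIT", due(QUARTERLY_MARKERS, 90)),
        ("ANNUAL_LAB_PANEL", due(ANNUAL_LAB_MARKERS, 365)),
        ("FUNDUS_OCULI", due(("FUNDUS_OCULI_DONE",), 730)),
    ]
    if phase == "B":
        actions.append(("CENTER_REVIEW", due(CENTER_MARKERS, 180)))
    actions.append(("ANNUAL_CENTER_SCREENING", due(CENTER_MARKERS, 365)))
    return tuple(actions)


def referral_check(
    patient_id: str,
    cohort: Cohort,
    *,
    repeated_count: int = 2,
) -> tuple[str, tuple[str, ...]]:
    """Specialist-referral level (URGENT dominates PROGRAMMABLE dominates NONE)."""
    row = cohort.patients[cohort.patients["patient_id"] == patient_id]
    if row.empty:
        raise KeyError(f"unknown patient {patient_id!r}")
    events = sorted(row.iloc[0]["event_flags"])
    if events:
        return "URGENT", tuple(events)

    reasons = []
    o = _patient_obs(cohort, patient_id)
    fpg_hot = o[
        (o["code"] == "FPG_MGDL")
        & (o["value"] > REFERRAL_FPG)
        & in_window(o["date"], cohort.as_of, WINDOW_DAYS)
    ]
    if len(fpg_hot) >= repeated_count:
        reasons.append("REPEATED_FPG_GT_180")

    hba1c = o[o["code"] == "HBA1C_PCT"]
    hba1c = hba1c.assign(_ord=hba1c.index).sort_values(["date", "_ord"], kind="stable")
    last_two = hba1c["value"].tail(2)
    if len(last_two) == 2 and (last_two > REFERRAL_HBA1C).all():
        reasons.append("HBA1C_GT_6_5_TWICE")

    c = cohort.conditions
    new_comp = c[
        (c["patient_id"] == patient_id)
        & (c["condition"] != "T2D")
        & in_window(c["onset_date"], cohort.as_of, WINDOW_DAYS)
    ]
    if not new_comp.empty:
        reasons.append("NEW_COMPLICATION")

    if reasons:
        return "PROGRAMMABLE", tuple(reasons)
    return "NONE", ()


def route_cohort(cohort: Cohort, **kwargs) -> list[FollowUpAssignment]:
    """Phase, due actions and referral level for every patient.

    Batch equivalent of :func:`assign_phase` + :func:`due_actions` +
    :func:`referral_check`, computed with grouped scans so routing a whole
    panel is linear in the table sizes."""
    as_of = cohort.as_of
    pids = list(cohort.patients["patient_id"])
    phases = phases_for(cohort, pids, **kwargs)

    o = cohort.observations[cohort.observations["date"] <= as_of]

    def last_dates(codes) -> dict[str, pd.Timestamp]:
        sub = o[o["code"].isin(codes)]
        return sub.groupby("patient_id")["date"].max().to_dict()

    last_quarterly = last_dates(QUARTERLY_MARKERS)
    last_labs = last_dates(ANNUAL_LAB_MARKERS)
    last_fundus = last_dates(("FUNDUS_OCULI_DONE",))
    last_center = last_dates(CENTER_MARKERS)

    fpg_hot_counts = (
        o[(o["code"] == "FPG_MGDL") & (o["value"] > REFERRAL_FPG)
          & in_window(o["date"], as_of, WINDOW_DAYS)]
        .groupby("patient_id").size().to_dict()
    )
    h = o[o["code"] == "HBA1C_PCT"]
    h = h.assign(_ord=h.index).sort_values(["date", "_ord"], kind="stable")
    hba1c_twice = set(
        h.groupby("patient_id")["value"]
        .apply(lambda s: len(s) >= 2 and bool((s.tail(2) > REFERRAL_HBA1C).all()))
        .pipe(lambda s: s.index[s])
    )
    c = cohort.conditions
    new_comp = set(
        c.loc[(c["condition"] != "T2D")
              & in_window(c["onset_date"], as_of, WINDOW_DAYS), "patient_id"]
    )
    events = dict(zip(cohort.patients["patient_id"], cohort.patients["event_flags"]))

    out = []
    for pid in pids:
        phase = phases[pid]
        if phase == "SCREENING":
            actions: tuple = ()
        else:
            def due(table, days):
                last = table.get(pid)
                return as_of if last is None else last + pd.Timedelta(days=days)

            items = [
                ("QUARTERLY_VISIT", due(last_quarterly, 90)),
                ("ANNUAL_LAB_PANEL", due(last_labs, 365)),
                ("FUNDUS_OCULI", due(last_fundus, 730)),
            ]
            if phase == "B":
                items.append(("CENTER_REVIEW", due(last_center, 180)))
            items.append(("ANNUAL_CENTER_SCREENING", due(last_center, 365)))
            actions = tuple(items)

        ev = sorted(events.get(pid, ()))
        if ev:
            referral, reasons = "URGENT", tuple(ev)
        else:
            r = []
            if fpg_hot_counts.get(pid, 0) >= 2:
                r.append("REPEATED_FPG_GT_180")
            if pid in hba1c_twice:
                r.append("HBA1C_GT_6_5_TWICE")
            if pid in new_comp:
                r.append("NEW_COMPLICATION")
            referral, reasons = ("PROGRAMMABLE", tuple(r)) if r else ("NONE", ())
        out.append(FollowUpAssignment(pid, phase, actions, referral, reasons))
    return out
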
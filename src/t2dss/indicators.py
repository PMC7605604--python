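"""Care-quality indicators, cross-GP aggregation and self-audit metrics.

Eleven numerator/denominator indicators monitor the T2D care process and
outcomes per GP:

====  ================================================  ==================
id    numerator rule                                    denominator scope
====  ================================================  ==================
1.1   has a T2D condition                               all assisted
2.1   HbA1c measured in the last 12 months              enrolled T2D
2.2   full lipid profile in the last 12 months          enrolled T2D [*]_
2.3   arterial pressure measured in the last 12 months  enrolled T2D
2.4   BMI ever recorded                                 enrolled T2D
2.5   waist circumference ever recorded                 enrolled T2D
2.6   microalbuminuria in the last 12 months            enrolled T2D
2.7   creatinine in the last 12 months                  enrolled T2D
3.1   latest HbA1c <= 6.5 %                             enrolled T2D
3.2   latest LDL <= 130 mg/dl                           enrolled T2D
3.3   latest AP <= 130/80 mmHg                          enrolled hypertensive T2D
====  ================================================  ==================

.. [*] The lipid-profile measurement cannot be calculated for triglyceride
   values above 200 mg/dl; such patients are removed from both numerator
   and denominator of 2.2.

Each GP's ratio is compared with the project target; the indicator's LAP
(Acceptable Level of Performance) points are awarded when the target is
reached or exceeded.  The project mean is the unweighted mean of per-GP
ratios.  Target percentages and LAP points are project configuration
(a documented synthetic default ships with the package).

The self-audit view summarises four areas per GP: recording completeness,
adherence to the expected T2D prevalence, treatment of chronic disease
(outcome indicators 3.1-3.3) and contact intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .ehr_core import (
    WINDOW_DAYS,
    Cohort,
    latest_per_patient,
    patients_with_obs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IndicatorDefinition",
    "IndicatorResult",
    "INDICATOR_IDS",
    "default_registry",
    "load_targets",
    "enrolled_t2d_panel",
    "compute_indicator",
    "compute_all",
    "drug_usage",
    "complications_in_act",
    "self_audit",
    "HBA1C_TARGET_PCT",
    "LDL_TARGET_MGDL",
    "AP_TARGET",
    "TRIG_COMPUTABLE_MAX",
]

HBA1C_TARGET_PCT = 6.5  # inclusive <=
LDL_TARGET_MGDL = 130.0  # inclusive <=
AP_TARGET = (130.0, 80.0)  # inclusive <= on both
TRIG_COMPUTABLE_MAX = 200.0  # latest trig > 200 -> lipid profile not computable

LIPID_PANEL = ("LDL_MGDL", "HDL_MGDL", "TOTCHOL_MGDL", "TRIG_MGDL")

INDICATOR_IDS = ("1.1", "2.1", "2.2", "2.3", "2.4", "2.5", "2.6", "2.7", "3.1", "3.2", "3.3")

_NAMES = {
    "1.1": "T2D patients among all assisted",
    "2.1": "Diabetics with annual HbA1c",
    "2.2": "Diabetics with annual lipid profile",
    "2.3": "Diabetics with annual AP",
    "2.4": "Diabetics with BMI",
    "2.5": "Diabetics with waist",
    "2.6": "Diabetics with annual microalbuminuria",
    "2.7": "Diabetics with annual creatinine",
    "3.1": "Diabetics with HbA1c <= 6.5%",
    "3.2": "Diabetics with LDL <= 130 mg/dl",
    "3.3": "Hypertensive diabetics with AP <= 130/80 mmHg",
}

_SCOPES = {"1.1": "ALL_ASSISTED", "3.3": "ENROLLED_T2D_HYPERTENSIVE"}

#: Synthetic default project configuration (target ratio, LAP points per
#: indicator).  Real projects supply their own YAML.
DEFAULT_TARGETS: dict[str, tuple[float, float]] = {
    "1.1": (0.06, 5),
    "2.1": (0.80, 10),
    "2.2": (0.60, 10),
    "2.3": (0.80, 10),
    "2.4": (0.85, 5),
    "2.5": (0.70, 5),
    "2.6": (0.50, 10),
    "2.7": (0.70, 10),
    "3.1": (0.25, 15),
    "3.2": (0.50, 15),
    "3.3": (0.30, 15),
}


@dataclass(frozen=True)
class IndicatorDefinition:
    indicator_id: str
    name: str
    denominator_scope: str  # ALL_ASSISTED | ENROLLED_T2D | ENROLLED_T2D_HYPERTENSIVE
    window_days: int | None
    target: float
    lap_points: float

    def __post_init__(self):
        if not 0.0 <= self.target <= 1.0:
            raise ValueError(f"target must be in [0,1], got {self.target}")
        if self.window_days is not None and self.window_days <= 0:
            raise ValueError("window_days must be positive")


@dataclass(frozen=True)
class IndicatorResult:
    indicator_id: str
    gp_id: str
    numerator: int
    denominator: int
    ratio: float
    target: float
    distance: float
    lap_awarded: float
    empty_denominator: bool = False
    project_mean: float | None = None


def default_registry(
    targets: dict[str, tuple[float, float]] | None = None,
    *,
    bmi_waist_window: int | None = None,
) -> dict[str, IndicatorDefinition]:
    """Registry of the eleven indicator definitions.

    ``targets`` maps indicator id -> (target ratio, LAP points); BMI/waist
    indicators evaluate the whole record unless ``bmi_waist_window`` is set.
    """
    targets = dict(DEFAULT_TARGETS) if targets is None else targets
    windows: dict[str, int | None] = {
        "1.1": None,
        "2.1": WINDOW_DAYS,
        "2.2": WINDOW_DAYS,
        "2.3": WINDOW_DAYS,
        "2.4": bmi_waist_window,
        "2.5": bmi_waist_window,
        "2.6": WINDOW_DAYS,
        "2.7": WINDOW_DAYS,
        "3.1": None,
        "3.2": None,
        "3.3": None,
    }
    reg = {}
    for iid in INDICATOR_IDS:
        if iid not in targets:
            raise ValueError(f"missing target for indicator {iid}")
        t, lap = targets[iid]
        reg[iid] = IndicatorDefinition(
            iid, _NAMES[iid], _SCOPES.get(iid, "ENROLLED_T2D"), windows[iid], float(t), float(lap)
        )
    return reg


def load_targets(path) -> dict[str, tuple[float, float]]:
    """Load ``{indicator_id: {target: .., lap_points: ..}}`` from YAML."""
    raw = yaml.safe_load(Path(path).read_text("utf-8"))
    out = {}
    for iid, entry in raw.items():
        out[str(iid)] = (float(entry["target"]), float(entry["lap_points"]))
    return out


def enrolled_t2d_panel(
    cohort: Cohort, gp_id: str, *, require_consent: bool = True
) -> list[str]:
    """Patient ids of the GP's enrolled (and consenting) T2D panel."""
    t2d = cohort.has_condition("T2D")
    p = cohort.panel(gp_id)
    m = p["enrolled"] & p["patient_id"].isin(t2d)
    if require_consent:
        m &= p["consent"]
    return list(p.loc[m, "patient_id"])


def _membership(
    defn: IndicatorDefinition, cohort: Cohort, panel: list[str]
) -> tuple[set[str], set[str]]:
    """(numerator members, denominator members) among ``panel``."""
    iid = defn.indicator_id
    pop = set(panel)
    if iid == "1.1":
        return pop & cohort.has_condition("T2D"), pop
    if iid == "2.1":
        return pop & patients_with_obs(
            cohort, ("HBA1C_PCT", "HBA1C_MMOLMOL"), defn.window_days
        ), pop
    if iid == "2.2":
        trig_latest = latest_per_patient(cohort, "TRIG_MGDL")
        not_computable = set(trig_latest.index[trig_latest > TRIG_COMPUTABLE_MAX])
        denom = pop - not_computable
        full = denom.copy()
        for code in LIPID_PANEL:
            full &= patients_with_obs(cohort, code, defn.window_days)
        return full, denom
    if iid == "2.3":
        return pop & patients_with_obs(
            cohort, ("AP_SYS_MMHG", "AP_DIA_MMHG"), defn.window_days
        ), pop
    if iid == "2.4":
        return pop & patients_with_obs(cohort, "BMI_KGM2", defn.window_days), pop
    if iid == "2.5":
        return pop & patients_with_obs(cohort, "WAIST_CM", defn.window_days), pop
    if iid == "2.6":
        return pop & patients_with_obs(cohort, "MICROALBUMINURIA_MGL", defn.window_days), pop
    if iid == "2.7":
        return pop & patients_with_obs(cohort, "CREATININE_MGDL", defn.window_days), pop
    if iid == "3.1":
        latest = latest_per_patient(cohort, "HBA1C_PCT")
        return pop & set(latest.index[latest <= HBA1C_TARGET_PCT]), pop
    if iid == "3.2":
        latest = latest_per_patient(cohort, "LDL_MGDL")
        return pop & set(latest.index[latest <= LDL_TARGET_MGDL]), pop
    if iid == "3.3":
        sys = latest_per_patient(cohort, "AP_SYS_MMHG")
        dia = latest_per_patient(cohort, "AP_DIA_MMHG")
        ok = set(sys.index[sys <= AP_TARGET[0]]) & set(dia.index[dia <= AP_TARGET[1]])
        return pop & ok, pop
    raise ValueError(f"unknown indicator id {iid!r}")


def compute_indicator(
    defn: IndicatorDefinition,
    cohort: Cohort,
    gp_id: str,
    *,
    require_consent: bool = True,
) -> IndicatorResult:
    """One indicator ratio for one GP at ``cohort.as_of``."""
    if gp_id not in set(cohort.patients["gp_id"]):
        raise KeyError(f"unknown gp {gp_id!r}")
    if defn.denominator_scope == "ALL_ASSISTED":
        panel = list(cohort.panel(gp_id)["patient_id"])
    else:
        panel = enrolled_t2d_panel(cohort, gp_id, require_consent=require_consent)
        if defn.denominator_scope == "ENROLLED_T2D_HYPERTENSIVE":
            hyp = cohort.has_condition("HYPERTENSION")
            panel = [p for p in panel if p in hyp]
    num, denom = _membership(defn, cohort, panel)
    empty = len(denom) == 0
    if empty:
        logger.warning("indicator %s gp %s: empty denominator", defn.indicator_id, gp_id)
    ratio = 0.0 if empty else len(num) / len(denom)
    distance = ratio - defn.target
    lap = defn.lap_points if (not empty and ratio >= defn.target) else 0.0
    return IndicatorResult(
        defn.indicator_id, gp_id, len(num), len(denom), ratio, defn.target, distance, lap,
        empty_denominator=empty,
    )


def compute_all(
    cohort: Cohort,
    registry: dict[str, IndicatorDefinition] | None = None,
    *,
    require_consent: bool = True,
) -> dict[str, list[IndicatorResult]]:
    """All indicators for all GPs, with the project mean filled in.

    Returns ``{gp_id: [IndicatorResult, ...]}``; each result's
    ``project_mean`` is the unweighted mean of the per-GP ratios for that
    indicator (GPs with an empty denominator excluded from the mean).
    """
    registry = registry or default_registry()
    gps = sorted(set(cohort.patients["gp_id"]))
    per_gp: dict[str, dict[str, IndicatorResult]] = {g: {} for g in gps}
    for iid, defn in registry.items():
        results = [
            compute_indicator(defn, cohort, g, require_consent=require_consent) for g in gps
        ]
        valid = [r.ratio for r in results if not r.empty_denominator]
        mean = sum(valid) / len(valid) if valid else None
        for g, r in zip(gps, results):
            per_gp[g][iid] = IndicatorResult(**{**r.__dict__, "project_mean": mean})
    return {g: [per_gp[g][iid] for iid in registry] for g in gps}


def drug_usage(cohort: Cohort, gp_id: str, *, window_days: int = WINDOW_DAYS) -> dict[str, float]:
    """Fraction of the GP's enrolled T2D panel with each drug class prescribed
    in the window (descriptive report; carries no LAP points)."""
    from .ehr_core import DRUG_CLASSES, in_window

    panel = set(enrolled_t2d_panel(cohort, gp_id))
    if not panel:
        return {d: 0.0 for d in DRUG_CLASSES}
    rx = cohort.prescriptions
    rx = rx[rx["patient_id"].isin(panel) & in_window(rx["date"], cohort.as_of, window_days)]
    return {
        d: len(set(rx.loc[rx["drug_class"] == d, "patient_id"])) / len(panel)
        for d in DRUG_CLASSES
    }


def complications_in_act(cohort: Cohort, gp_id: str) -> dict[str, float]:
    """Fraction of the GP's enrolled T2D panel with each complication recorded."""
    from .ehr_core import CONDITION_CODES

    panel = set(enrolled_t2d_panel(cohort, gp_id))
    out = {}
    for cond in CONDITION_CODES:
        if cond == "T2D":
            continue
        members = cohort.has_condition(cond)
        out[cond] = (len(panel & members) / len(panel)) if panel else 0.0
    return out


# Fields scored for recording completeness: (codes, window).
COMPLETENESS_FIELDS: tuple[tuple[tuple[str, ...], int | None], ...] = (
    (("HBA1C_PCT", "HBA1C_MMOLMOL"), WINDOW_DAYS),
    (("LDL_MGDL",), WINDOW_DAYS),
    (("AP_SYS_MMHG", "AP_DIA_MMHG"), WINDOW_DAYS),
    (("BMI_KGM2",), None),
    (("WAIST_CM",), None),
    (("MICROALBUMINURIA_MGL",), WINDOW_DAYS),
    (("CREATININE_MGDL",), WINDOW_DAYS),
)


def self_audit(
    cohort: Cohort,
    gp_id: str,
    *,
    reference_prevalence: float = 0.06,
    registry: dict[str, IndicatorDefinition] | None = None,
) -> dict[str, float]:
    """Four self-audit area scores for one GP.

    * ``recording_completeness`` — mean, over the enrolled panel, of the
      fraction of the seven audited fields recorded in their windows;
    * ``adherence_to_prevalence`` — absolute distance between the GP's T2D
      prevalence and the reference prevalence;
    * ``treatment_of_chronic_disease`` — mean of outcome indicators 3.1-3.3;
    * ``contact_intensity`` — records (observations + prescriptions) per
      enrolled patient over the last 365 days.
    """
    from .ehr_core import in_window

    registry = registry or default_registry()
    panel = enrolled_t2d_panel(cohort, gp_id)

    if panel:
        field_sets = [
            patients_with_obs(cohort, codes, win) for codes, win in COMPLETENESS_FIELDS
        ]
        completeness = sum(
            sum(1 for s in field_sets if pid in s) / len(COMPLETENESS_FIELDS)
            for pid in panel
        ) / len(panel)
    else:
        completeness = 0.0

    assisted = cohort.panel(gp_id)
    t2d = cohort.has_condition("T2D")
    prevalence = (
        assisted["patient_id"].isin(t2d).mean() if len(assisted) else 0.0
    )

    treat = [
        compute_indicator(registry[iid], cohort, gp_id).ratio for iid in ("3.1", "3.2", "3.3")
    ]

    if panel:
        o, r = cohort.observations, cohort.prescriptions
        n_rec = int(
            (o["patient_id"].isin(panel) & in_window(o["date"], cohort.as_of, WINDOW_DAYS)).sum()
        ) + int(
            (r["patient_id"].isin(panel) & in_window(r["date"], cohort.as_of, WINDOW_DAYS)).sum()
        )
        intensity = n_rec / len(panel)
    else:
        intensity = 0.0

    return {
        "recording_completeness": float(completeness),
        "adherence_to_prevalence": float(abs(prevalence - reference_prevalence)),
        "treatment_of_chronic_disease": float(sum(treat) / 3.0),
        "contact_intensity": float(intensity),
    }
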
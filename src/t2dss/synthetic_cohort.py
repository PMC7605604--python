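"""Seeded synthetic GP panels with the statistical structure the DSS consumes.

The generator emulates a primary-care panel: a configurable number of
GPs, a T2D prevalence, per-complication rates among diabetics, drug
prescription rates, and per-code observation streams.  Each observation
code follows a Poisson schedule (expected one measurement per
``lab_schedule[code]`` days over the simulated history) thinned by a
per-code missingness probability; values are drawn from a per-code
truncated normal.  All parameters are explicitly synthetic defaults —
plausible for an adult Italian GP panel, not estimates of any real
database.

Generation is a pure function of ``(config, seed)``: every table and
observation code draws from its own RNG stream derived from the seed,
so regenerating with the same configuration is byte-identical.

``generate_quality_labels`` attaches a 5-level ordinal care-quality
label to every enrolled patient using a documented deterministic rule
(the number of the seven per-patient indicator criteria met, mapped
monotonically onto the Likert scale), optionally corrupted by label-flip
noise.  This gives the downstream classifier a recoverable signal whose
strength is controlled by a single knob.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.stats import truncnorm

from .ehr_core import Cohort, cohort_from_records, validate_cohort
from .quality_model import (
    LIKERT_LEVELS,
    QualityDataset,
    build_quality_dataset,
    rule_labels_from_scores,
    rule_scores,
)

__all__ = ["CohortConfig", "generate_cohort", "generate_quality_labels", "load_config"]

#: Mean inter-measurement interval (days) per code for T2D patients.
DEFAULT_LAB_SCHEDULE: dict[str, float] = {
    "HBA1C_PCT": 180,
    "FPG_MGDL": 150,
    "LDL_MGDL": 365,
    "HDL_MGDL": 365,
    "TOTCHOL_MGDL": 365,
    "TRIG_MGDL": 365,
    "AP_SYS_MMHG": 90,  # systolic/diastolic are generated as pairs
    "BMI_KGM2": 240,
    "WAIST_CM": 400,
    "WEIGHT_KG": 240,
    "HEIGHT_CM": 1400,
    "MICROALBUMINURIA_MGL": 365,
    "CREATININE_MGDL": 365,
    "FUNDUS_OCULI_DONE": 730,
    "ECG_DONE": 365,
    "URINE_EXAM_DONE": 400,
}

#: Sparser schedule for patients without T2D.
NON_T2D_LAB_SCHEDULE: dict[str, float] = {
    "FPG_MGDL": 540,
    "AP_SYS_MMHG": 180,
    "BMI_KGM2": 365,
    "WEIGHT_KG": 365,
    "HEIGHT_CM": 1400,
    "LDL_MGDL": 730,
    "HDL_MGDL": 730,
    "TOTCHOL_MGDL": 730,
    "TRIG_MGDL": 730,
    "CREATININE_MGDL": 730,
    "HBA1C_MMOLMOL": 1095,
    "OGTT2H_MGDL": 1460,
    "URINE_EXAM_DONE": 730,
    "ECG_DONE": 730,
}

#: (mean, sd, lower truncation) per code.
DEFAULT_VALUE_DISTRIBUTIONS: dict[str, tuple[float, float, float]] = {
    "HBA1C_PCT": (7.1, 1.1, 4.0),
    "HBA1C_MMOLMOL": (42.0, 7.0, 20.0),
    "FPG_MGDL": (118.0, 28.0, 45.0),
    "OGTT2H_MGDL": (150.0, 35.0, 60.0),
    "LDL_MGDL": (128.0, 30.0, 30.0),
    "HDL_MGDL": (48.0, 12.0, 15.0),
    "TOTCHOL_MGDL": (195.0, 35.0, 80.0),
    "TRIG_MGDL": (160.0, 60.0, 40.0),
    "AP_SYS_MMHG": (133.0, 15.0, 80.0),
    "AP_DIA_MMHG": (80.0, 10.0, 40.0),
    "BMI_KGM2": (29.0, 4.5, 15.0),
    "WAIST_CM": (100.0, 12.0, 55.0),
    "WEIGHT_KG": (82.0, 15.0, 35.0),
    "HEIGHT_CM": (167.0, 10.0, 130.0),
    "MICROALBUMINURIA_MGL": (25.0, 20.0, 0.0),
    "CREATININE_MGDL": (0.95, 0.25, 0.2),
}

#: Overrides applied to the non-T2D streams: a non-diabetic panel has
#: near-normal glycemia.
NON_T2D_VALUE_OVERRIDES: dict[str, tuple[float, float, float]] = {
    "FPG_MGDL": (95.0, 12.0, 45.0),
    "OGTT2H_MGDL": (120.0, 30.0, 50.0),
}

DEFAULT_COMPLICATION_RATES = {
    "CHD": 0.10,
    "ICTUS": 0.04,
    "PERIPHERAL_ARTERIAL_DISEASE": 0.05,
    "RETINOPATHY": 0.08,
    "HYPERTENSION": 0.50,  # prevalence of hypertension in diabetes ~50%
}

DEFAULT_DRUG_RATES = {
    "METFORMIN": 0.60,
    "SULFONYLUREA": 0.20,
    "OTHER_ANTIDIABETIC": 0.15,
    "STATIN": 0.40,
}


class CohortConfig(BaseModel):
    """Parameters of the synthetic GP panel."""

    n_patients: int = Field(default=2000, gt=0)
    n_gps: int = Field(default=10, gt=0)
    t2d_prevalence: float = Field(default=0.08, ge=0.0, le=1.0)
    complication_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COMPLICATION_RATES)
    )
    hypertension_rate_non_t2d: float = Field(default=0.20, ge=0.0, le=1.0)
    insulin_rate_among_t2d: float = Field(default=0.15, ge=0.0, le=1.0)
    drug_rates_among_t2d: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DRUG_RATES)
    )
    antihypertensive_rate_among_hypertensive: float = Field(default=0.80, ge=0.0, le=1.0)
    oral_antidiabetic_rate_non_t2d: float = Field(default=0.02, ge=0.0, le=1.0)
    enrollment_rate: float = Field(default=0.90, ge=0.0, le=1.0)
    consent_rate_non_enrolled: float = Field(default=0.50, ge=0.0, le=1.0)
    risk_flag_rate: float = Field(default=0.08, ge=0.0, le=1.0)
    event_flag_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    age_range: tuple[int, int] = (30, 90)
    history_days: int = Field(default=730, gt=0)
    onset_horizon_days: int = Field(default=2920, gt=0)
    lab_schedule: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_LAB_SCHEDULE)
    )
    missingness: dict[str, float] = Field(default_factory=dict)
    default_missingness: float = Field(default=0.20, ge=0.0, le=1.0)
    value_distributions: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_VALUE_DISTRIBUTIONS)
    )
    as_of: str = "2019-12-31"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for code, p in {**self.complication_rates, **self.missingness}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {code} outside [0,1]: {p}")
        for code, iv in self.lab_schedule.items():
            if iv <= 0:
                raise ValueError(f"lab_schedule interval for {code} must be > 0")
        for code, (mean, sd, lower) in self.value_distributions.items():
            if sd <= 0:
                raise ValueError(f"value sd for {code} must be > 0")
            if lower > mean + 6 * sd:
                raise ValueError(
                    f"impossible truncation for {code}: lower bound {lower} "
                    f"above mean + 6 sd"
                )
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] < 18:
            raise ValueError("age_range must be (lo, hi) with 18 <= lo < hi")
        return self

    def miss(self, code: str) -> float:
        return self.missingness.get(code, self.default_missingness)


def load_config(path) -> CohortConfig:
    return CohortConfig(**(yaml.safe_load(Path(path).read_text("utf-8")) or {}))


def _rng(seed: int, *key: str) -> np.random.Generator:
    """Independent stream per (seed, key): adding streams never perturbs others."""
    entropy = (int(seed),) + tuple(zlib.crc32(k.encode()) for k in key)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _truncnorm(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _stream_observations(cfg, rng, pids, code, interval, as_of, overrides=None):
    """Thinned-Poisson observation stream of one code over a patient subset."""
    lam = cfg.history_days / interval * (1.0 - cfg.miss(code))
    counts = rng.poisson(lam, size=len(pids))
    total = int(counts.sum())
    if total == 0:
        return []
    days_back = rng.integers(1, cfg.history_days + 1, size=total)
    if code.endswith("_DONE"):
        values = np.ones(total)
    else:
        mean, sd, lower = (overrides or {}).get(code, cfg.value_distributions[code])
        values = np.round(_truncnorm(rng, mean, sd, lower, total), 2)
    rep_pid = np.repeat(pids, counts)
    out = []
    for pid, back, val in zip(rep_pid, days_back, values):
        out.append(
            {
                "patient_id": pid,
                "code": code,
                "value": float(val),
                "date": (as_of - pd.Timedelta(days=int(back))).strftime("%Y-%m-%d"),
            }
        )
    return out


#: Lipid profile is ordered as one panel: shared draw dates, per-code skips.
LIPID_PANEL_CODES = ("TRIG_MGDL", "LDL_MGDL", "HDL_MGDL", "TOTCHOL_MGDL")


def _panel_observations(cfg, rng, pids, codes, interval, as_of, overrides=None):
    """Multi-code panel drawn on shared dates; each code independently skipped
    with its own missingness probability."""
    lam = cfg.history_days / interval
    counts = rng.poisson(lam, size=len(pids))
    total = int(counts.sum())
    if total == 0:
        return []
    days_back = rng.integers(1, cfg.history_days + 1, size=total)
    rep_pid = np.repeat(pids, counts)
    out = []
    for code in codes:
        keep = rng.random(total) >= cfg.miss(code)
        n_keep = int(keep.sum())
        if n_keep == 0:
            continue
        mean, sd, lower = (overrides or {}).get(code, cfg.value_distributions[code])
        values = np.round(_truncnorm(rng, mean, sd, lower, n_keep), 2)
        for pid, back, val in zip(rep_pid[keep], days_back[keep], values):
            out.append(
                {
                    "patient_id": pid,
                    "code": code,
                    "value": float(val),
                    "date": (as_of - pd.Timedelta(days=int(back))).strftime("%Y-%m-%d"),
                }
            )
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a validated synthetic cohort; deterministic in (config, seed)."""
    cfg = config
    as_of = pd.Timestamp(cfg.as_of)
    n = cfg.n_patients
    pids = np.array([f"P{i:06d}" for i in range(1, n + 1)])

    rng_p = _rng(cfg.seed, "patients")
    gp_ids = np.array([f"G{i:03d}" for i in rng_p.integers(1, cfg.n_gps + 1, size=n)])
    age_days = rng_p.integers(
        cfg.age_range[0] * 365, cfg.age_range[1] * 365, size=n
    )
    birth = [(as_of - pd.Timedelta(days=int(d))).strftime("%Y-%m-%d") for d in age_days]
    sex = np.where(rng_p.random(n) < 0.5, "F", "M")

    rng_t = _rng(cfg.seed, "t2d")
    is_t2d = rng_t.random(n) < cfg.t2d_prevalence
    onset_back = rng_t.integers(0, cfg.onset_horizon_days + 1, size=n)

    rng_f = _rng(cfg.seed, "flags")
    from .ehr_core import EVENT_FLAGS, RISK_FLAGS

    risk_draw = rng_f.random((n, len(RISK_FLAGS))) < cfg.risk_flag_rate
    event_draw = rng_f.random((n, len(EVENT_FLAGS))) < cfg.event_flag_rate
    enrolled = is_t2d & (rng_f.random(n) < cfg.enrollment_rate)
    consent = enrolled | (rng_f.random(n) < cfg.consent_rate_non_enrolled)

    patients = []
    for i in range(n):
        patients.append(
            {
                "patient_id": pids[i],
                "gp_id": gp_ids[i],
                "birth_date": birth[i],
                "sex": sex[i],
                "risk_flags": frozenset(
                    f for f, hit in zip(RISK_FLAGS, risk_draw[i]) if hit
                ),
                "event_flags": frozenset(
                    f for f, hit in zip(EVENT_FLAGS, event_draw[i]) if hit and is_t2d[i]
                ),
                "enrolled": bool(enrolled[i]),
                "consent": bool(consent[i]),
            }
        )

    conditions = []
    rng_c = _rng(cfg.seed, "conditions")
    for i in np.flatnonzero(is_t2d):
        conditions.append(
            {
                "patient_id": pids[i],
                "condition": "T2D",
                "onset_date": (as_of - pd.Timedelta(days=int(onset_back[i]))).strftime(
                    "%Y-%m-%d"
                ),
            }
        )
    for cond, rate in sorted(cfg.complication_rates.items()):
        hit = rng_c.random(n) < rate
        back = rng_c.integers(0, 1825, size=n)
        for i in np.flatnonzero(hit & is_t2d):
            conditions.append(
                {
                    "patient_id": pids[i],
                    "condition": cond,
                    "onset_date": (
                        as_of - pd.Timedelta(days=int(back[i]))
                    ).strftime("%Y-%m-%d"),
                }
            )
    hyp_bg = rng_c.random(n) < cfg.hypertension_rate_non_t2d
    back = rng_c.integers(0, 1825, size=n)
    hyp_t2d = {
        c["patient_id"] for c in conditions if c["condition"] == "HYPERTENSION"
    }
    for i in np.flatnonzero(hyp_bg & ~is_t2d):
        conditions.append(
            {
                "patient_id": pids[i],
                "condition": "HYPERTENSION",
                "onset_date": (as_of - pd.Timedelta(days=int(back[i]))).strftime(
                    "%Y-%m-%d"
                ),
            }
        )
    hypertensive = hyp_t2d | {pids[i] for i in np.flatnonzero(hyp_bg & ~is_t2d)}

    prescriptions = []
    rng_rx = _rng(cfg.seed, "prescriptions")

    def add_rx(mask, drug):
        n_rx = 1 + rng_rx.poisson(2, size=n)
        for i in np.flatnonzero(mask):
            backs = rng_rx.integers(1, cfg.history_days + 1, size=n_rx[i])
            for b in backs:
                prescriptions.append(
                    {
                        "patient_id": pids[i],
                        "drug_class": drug,
                        "date": (as_of - pd.Timedelta(days=int(b))).strftime("%Y-%m-%d"),
                    }
                )

    add_rx(is_t2d & (rng_rx.random(n) < cfg.insulin_rate_among_t2d), "INSULIN")
    for drug, rate in sorted(cfg.drug_rates_among_t2d.items()):
        add_rx(is_t2d & (rng_rx.random(n) < rate), drug)
    add_rx(~is_t2d & (rng_rx.random(n) < cfg.oral_antidiabetic_rate_non_t2d), "METFORMIN")
    is_hyp = np.isin(pids, sorted(hypertensive))
    add_rx(
        is_hyp & (rng_rx.random(n) < cfg.antihypertensive_rate_among_hypertensive),
        "ANTIHYPERTENSIVE",
    )

    observations = []
    t2d_pids = pids[is_t2d]
    other_pids = pids[~is_t2d]
    for code, interval in sorted(cfg.lab_schedule.items()):
        if code in LIPID_PANEL_CODES and code != "TRIG_MGDL":
            continue
        rng_o = _rng(cfg.seed, "obs", "t2d", code)
        if code == "TRIG_MGDL":
            observations.extend(
                _panel_observations(cfg, rng_o, t2d_pids, LIPID_PANEL_CODES,
                                    interval, as_of)
            )
        else:
            observations.extend(
                _stream_observations(cfg, rng_o, t2d_pids, code, interval, as_of)
            )

    # Non-T2D streams
    for code, interval in sorted(NON_T2D_LAB_SCHEDULE.items()):
        if code in LIPID_PANEL_CODES and code != "TRIG_MGDL":
            continue
        rng_o = _rng(cfg.seed, "obs", "other", code)
        if code == "TRIG_MGDL":
            observations.extend(
                _panel_observations(cfg, rng_o, other_pids, LIPID_PANEL_CODES,
                                    interval, as_of,
                                    overrides=NON_T2D_VALUE_OVERRIDES)
            )
        else:
            observations.extend(
                _stream_observations(
                    cfg, rng_o, other_pids, code, interval, as_of,
                    overrides=NON_T2D_VALUE_OVERRIDES,
                )
            )

    # Pair a diastolic reading with every systolic one (same date).
    rng_dia = _rng(cfg.seed, "obs", "dia")
    sys_rows = [o for o in observations if o["code"] == "AP_SYS_MMHG"]
    mean, sd, lower = cfg.value_distributions["AP_DIA_MMHG"]
    dia_vals = np.round(_truncnorm(rng_dia, mean, sd, lower, len(sys_rows)), 2)
    for o, v in zip(sys_rows, dia_vals):
        observations.append(
            {"patient_id": o["patient_id"], "code": "AP_DIA_MMHG", "value": float(v),
             "date": o["date"]}
        )

    cohort = cohort_from_records(
        patients, observations, conditions, prescriptions, as_of=cfg.as_of,
        validate=False,
    )
    validate_cohort(cohort)
    return cohort


def generate_quality_labels(
    cohort: Cohort, rule_noise: float = 0.0, seed: int = 0
) -> QualityDataset:
    """Ordinal 1-5 care-quality labels for every enrolled patient.

    With ``rule_noise`` 0 the label is a deterministic function of the seven
    per-patient indicator criteria (all met -> 1 Excellent, ..., three or
    fewer -> 5 Poor).  With noise, each label is independently replaced,
    with probability ``rule_noise``, by a uniform draw over the full 5-point
    scale — so at ``rule_noise`` 1 the labels carry no information about the
    features at all.
    """
    if not 0.0 <= rule_noise <= 1.0:
        raise ValueError(f"rule_noise must be in [0,1], got {rule_noise}")
    if len(cohort.patients) == 0:
        raise ValueError("cohort is empty")
    scores = rule_scores(cohort)["score"]
    labels = rule_labels_from_scores(scores)
    if rule_noise > 0:
        rng = _rng(seed, "labels")
        flip = rng.random(len(labels)) < rule_noise
        noisy = rng.integers(1, len(LIKERT_LEVELS) + 1, size=len(labels))
        labels = pd.Series(
            np.where(flip, noisy, labels.to_numpy()), index=labels.index, dtype=int
        )
    return build_quality_dataset(cohort, labels)
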
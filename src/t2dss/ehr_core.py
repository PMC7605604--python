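"""Flat longitudinal EHR data model for GP panels.

The toolkit operates on four flat tables extracted from GP electronic
health records: a patient registry, dated coded numeric observations,
condition (problem-list) records, and prescription records.  A
:class:`Cohort` bundles the four tables together with an ``as_of``
evaluation date; every downstream rule engine (enrollment, screening,
indicators, follow-up routing) is a pure function of a validated cohort.

Conventions fixed here and relied on everywhere else:

* **Temporal windows.**  "Last 12 months" means the 365-day lookback
  ``0 <= (as_of - date).days <= 365`` — an observation dated exactly 365
  days before ``as_of`` is *inside* the window, 366 days is outside.
  No leap-year adjustment is made.
* **Units.**  Each observation code carries one canonical unit (encoded
  in its name, e.g. ``FPG_MGDL``); there is no per-row unit field.
  HbA1c exists in both DCCT percent (``HBA1C_PCT``, canonical for all
  threshold rules) and IFCC mmol/mol (``HBA1C_MMOLMOL``, used only by
  the 42-48 mmol/mol dysglycemia band); no conversion is performed.
* **Ties.**  Two observations of the same code on the same date: the
  one later in file order wins (a warning is logged).
* **Serialization.**  RFC-4180 CSV with a header row, UTF-8, ISO-8601
  dates, ``.`` decimal point; a JSONL mirror is accepted on read and
  available on write.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OBSERVATION_CODES",
    "DONE_CODES",
    "GLYCEMIC_CODES",
    "CONDITION_CODES",
    "EXCLUSION_CONDITIONS",
    "DRUG_CLASSES",
    "ANTIDIABETIC_NON_INSULIN",
    "RISK_FLAGS",
    "EVENT_FLAGS",
    "WINDOW_DAYS",
    "PatientRecord",
    "Observation",
    "ConditionRecord",
    "PrescriptionRecord",
    "Cohort",
    "CohortValidationError",
    "cohort_from_records",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "latest_value",
    "latest_per_patient",
    "patients_with_obs",
    "in_window",
    "age_years",
]

# ---------------------------------------------------------------------------
# Closed vocabularies

OBSERVATION_CODES: tuple[str, ...] = (
    "HBA1C_PCT",
    "HBA1C_MMOLMOL",
    "FPG_MGDL",
    "OGTT2H_MGDL",
    "LDL_MGDL",
    "HDL_MGDL",
    "TOTCHOL_MGDL",
    "TRIG_MGDL",
    "AP_SYS_MMHG",
    "AP_DIA_MMHG",
    "BMI_KGM2",
    "WAIST_CM",
    "WEIGHT_KG",
    "HEIGHT_CM",
    "MICROALBUMINURIA_MGL",
    "CREATININE_MGDL",
    "FUNDUS_OCULI_DONE",
    "ECG_DONE",
    "URINE_EXAM_DONE",
)

#: Procedure-performed markers; the only admissible value is 1.
DONE_CODES = frozenset(c for c in OBSERVATION_CODES if c.endswith("_DONE"))

#: Codes that count as "glycemic checks" (potential-T2D heuristic).
GLYCEMIC_CODES = frozenset({"HBA1C_PCT", "HBA1C_MMOLMOL", "FPG_MGDL", "OGTT2H_MGDL"})

CONDITION_CODES: tuple[str, ...] = (
    "T2D",
    "CHD",
    "ICTUS",
    "PERIPHERAL_ARTERIAL_DISEASE",
    "RETINOPATHY",
    "HYPERTENSION",
)

#: Complications whose presence excludes a T2D patient from automatic enrollment.
EXCLUSION_CONDITIONS = frozenset(
    {"CHD", "ICTUS", "PERIPHERAL_ARTERIAL_DISEASE", "RETINOPATHY"}
)

DRUG_CLASSES: tuple[str, ...] = (
    "INSULIN",
    "METFORMIN",
    "SULFONYLUREA",
    "OTHER_ANTIDIABETIC",
    "ANTIHYPERTENSIVE",
    "STATIN",
)

ANTIDIABETIC_NON_INSULIN = frozenset({"METFORMIN", "SULFONYLUREA", "OTHER_ANTIDIABETIC"})

RISK_FLAGS: tuple[str, ...] = (
    "PHYSICAL_INACTIVITY",
    "FAMILY_HISTORY_T2D",
    "HIGH_RISK_ETHNICITY",
    "GESTATIONAL_DIABETES_HISTORY",
    "MACROSOMIC_BIRTH_HISTORY",
    "INSULIN_RESISTANCE",
    "CVD_EVIDENCE",
    "PRIOR_IGT",
    "PRIOR_IFG",
)

EVENT_FLAGS: tuple[str, ...] = (
    "FOOT_ULCER",
    "SEVERE_HYPOGLYCEMIA",
    "PREGNANCY",
    "METABOLIC_INSTABILITY",
)

#: Fixed length, in days, of the "last 12 months" lookback window.
WINDOW_DAYS = 365

_TABLES = ("patients", "observations", "conditions", "prescriptions")

_COLUMNS: dict[str, list[str]] = {
    "patients": [
        "patient_id",
        "gp_id",
        "birth_date",
        "sex",
        "risk_flags",
        "event_flags",
        "enrolled",
        "consent",
    ],
    "observations": ["patient_id", "code", "value", "date"],
    "conditions": ["patient_id", "condition", "onset_date"],
    "prescriptions": ["patient_id", "drug_class", "date"],
}


# ---------------------------------------------------------------------------
# Record types

@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    gp_id: str
    birth_date: str  # ISO date
    sex: str = "F"
    risk_flags: frozenset[str] = frozenset()
    event_flags: frozenset[str] = frozenset()
    enrolled: bool = False
    consent: bool = True


@dataclass(frozen=True)
class Observation:
    patient_id: str
    code: str
    value: float
    date: str


@dataclass(frozen=True)
class ConditionRecord:
    patient_id: str
    condition: str
    onset_date: str


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    drug_class: str
    date: str


class CohortValidationError(ValueError):
    """Raised when cohort tables violate the schema; carries row-level issues."""

    def __init__(self, issues: Sequence[str]):
        self.issues = list(issues)
        preview = "; ".join(self.issues[:5])
        more = "" if len(self.issues) <= 5 else f" (+{len(self.issues) - 5} more)"
        super().__init__(f"{len(self.issues)} validation issue(s): {preview}{more}")


@dataclass
class Cohort:
    """Validated bundle of the four EHR tables at an evaluation date."""

    patients: pd.DataFrame
    observations: pd.DataFrame
    conditions: pd.DataFrame
    prescriptions: pd.DataFrame
    as_of: pd.Timestamp

    def __post_init__(self) -> None:
        self.as_of = pd.Timestamp(self.as_of)

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.patients["patient_id"])

    def panel(self, gp_id: str) -> pd.DataFrame:
        """All assisted patients of one GP."""
        return self.patients[self.patients["gp_id"] == gp_id]

    def has_condition(self, condition: str) -> set[str]:
        """Patient ids carrying ``condition`` with onset <= as_of."""
        c = self.conditions
        m = (c["condition"] == condition) & (c["onset_date"] <= self.as_of)
        return set(c.loc[m, "patient_id"])

    @classmethod
    def empty(cls, as_of) -> "Cohort":
        return cohort_from_records(as_of=as_of)


# ---------------------------------------------------------------------------
# Construction & validation

def _as_flagset(v) -> frozenset[str]:
    if isinstance(v, frozenset):
        return v
    if isinstance(v, (set, list, tuple)):
        return frozenset(str(x) for x in v if str(x))
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return frozenset()
    s = str(v).strip()
    return frozenset(p for p in s.split("|") if p)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _normalize_frames(
    patients: pd.DataFrame,
    observations: pd.DataFrame,
    conditions: pd.DataFrame,
    prescriptions: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    issues: list[str] = []

    p = patients.reindex(columns=_COLUMNS["patients"]).copy()
    p["patient_id"] = p["patient_id"].astype(str)
    p["gp_id"] = p["gp_id"].astype(str)
    p["birth_date"] = pd.to_datetime(p["birth_date"], format="mixed")
    p["sex"] = p["sex"].astype(str)
    p["risk_flags"] = p["risk_flags"].map(_as_flagset)
    p["event_flags"] = p["event_flags"].map(_as_flagset)
    for col in ("enrolled", "consent"):
        try:
            p[col] = p[col].map(_as_bool)
        except ValueError as exc:
            issues.append(f"patients: column {col}: {exc}")
            p[col] = False

    o = observations.reindex(columns=_COLUMNS["observations"]).copy()
    o["patient_id"] = o["patient_id"].astype(str)
    o["code"] = o["code"].astype(str)
    o["value"] = pd.to_numeric(o["value"], errors="coerce")
    o["date"] = pd.to_datetime(o["date"], format="mixed")

    c = conditions.reindex(columns=_COLUMNS["conditions"]).copy()
    c["patient_id"] = c["patient_id"].astype(str)
    c["condition"] = c["condition"].astype(str)
    c["onset_date"] = pd.to_datetime(c["onset_date"], format="mixed")

    r = prescriptions.reindex(columns=_COLUMNS["prescriptions"]).copy()
    r["patient_id"] = r["patient_id"].astype(str)
    r["drug_class"] = r["drug_class"].astype(str)
    r["date"] = pd.to_datetime(r["date"], format="mixed")

    for df in (p, o, c, r):
        df.reset_index(drop=True, inplace=True)
    return p, o, c, r, issues


def validate_cohort(cohort: Cohort) -> None:
    """Check every schema invariant; raise :class:`CohortValidationError` listing
    each offending row (1-based data-row numbers)."""
    issues: list[str] = []
    as_of = cohort.as_of
    p, o, c, r = cohort.patients, cohort.observations, cohort.conditions, cohort.prescriptions

    dup = p["patient_id"].duplicated()
    for i in p.index[dup]:
        issues.append(f"patients row {i + 1}: duplicate patient_id {p.at[i, 'patient_id']!r}")
    for i in p.index[p["gp_id"].str.len() == 0]:
        issues.append(f"patients row {i + 1}: empty gp_id")
    for i in p.index[~p["sex"].isin(["M", "F"])]:
        issues.append(f"patients row {i + 1}: sex must be M or F, got {p.at[i, 'sex']!r}")
    for i in p.index:
        bad = p.at[i, "risk_flags"] - set(RISK_FLAGS)
        if bad:
            issues.append(f"patients row {i + 1}: unknown risk_flags {sorted(bad)}")
        bad = p.at[i, "event_flags"] - set(EVENT_FLAGS)
        if bad:
            issues.append(f"patients row {i + 1}: unknown event_flags {sorted(bad)}")

    known = set(p["patient_id"])
    birth = dict(zip(p["patient_id"], p["birth_date"]))

    for i in o.index[~o["code"].isin(OBSERVATION_CODES)]:
        issues.append(f"observations row {i + 1}: unknown code {o.at[i, 'code']!r}")
    for i in o.index[~o["patient_id"].isin(known)]:
        issues.append(
            f"observations row {i + 1}: unknown patient {o.at[i, 'patient_id']!r}"
        )
    for i in o.index[~np.isfinite(o["value"].to_numpy(dtype=float))]:
        issues.append(f"observations row {i + 1}: non-finite value")
    for i in o.index[(o["value"] < 0) & np.isfinite(o["value"].to_numpy(dtype=float))]:
        issues.append(f"observations row {i + 1}: negative value {o.at[i, 'value']}")
    done = o["code"].isin(DONE_CODES)
    for i in o.index[done & (o["value"] != 1)]:
        issues.append(
            f"observations row {i + 1}: {o.at[i, 'code']} value must be 1, "
            f"got {o.at[i, 'value']}"
        )
    for i in o.index[o["date"] > as_of]:
        issues.append(f"observations row {i + 1}: date after as_of {as_of.date()}")
    ok = o["patient_id"].isin(known)
    if ok.any():
        bd = pd.to_datetime(o.loc[ok, "patient_id"].map(birth))
        for i in o.index[ok][(o.loc[ok, "date"] <= bd).to_numpy()]:
            issues.append(
                f"observations row {i + 1}: date not after patient birth_date"
            )

    for i in c.index[~c["condition"].isin(CONDITION_CODES)]:
        issues.append(f"conditions row {i + 1}: unknown condition {c.at[i, 'condition']!r}")
    for i in c.index[~c["patient_id"].isin(known)]:
        issues.append(f"conditions row {i + 1}: unknown patient {c.at[i, 'patient_id']!r}")
    for i in c.index[c["onset_date"] > as_of]:
        issues.append(f"conditions row {i + 1}: onset_date after as_of")
    dup = c.duplicated(subset=["patient_id", "condition"])
    for i in c.index[dup]:
        issues.append(
            f"conditions row {i + 1}: duplicate (patient_id, condition) "
            f"({c.at[i, 'patient_id']!r}, {c.at[i, 'condition']!r})"
        )

    for i in r.index[~r["drug_class"].isin(DRUG_CLASSES)]:
        issues.append(
            f"prescriptions row {i + 1}: unknown drug_class {r.at[i, 'drug_class']!r}"
        )
    for i in r.index[~r["patient_id"].isin(known)]:
        issues.append(f"prescriptions row {i + 1}: unknown patient {r.at[i, 'patient_id']!r}")
    for i in r.index[r["date"] > as_of]:
        issues.append(f"prescriptions row {i + 1}: date after as_of")

    same_day = o.duplicated(subset=["patient_id", "code", "date"], keep="last")
    if same_day.any():
        logger.warning(
            "%d same-date duplicate observation(s); the last row in file order wins",
            int(same_day.sum()),
        )

    if issues:
        raise CohortValidationError(issues)


def cohort_from_records(
    patients: Iterable = (),
    observations: Iterable = (),
    conditions: Iterable = (),
    prescriptions: Iterable = (),
    as_of="2019-12-31",
    validate: bool = True,
) -> Cohort:
    """Build a :class:`Cohort` from record dataclasses or plain dicts."""

    def frame(rows, table) -> pd.DataFrame:
        recs = [r.__dict__ if hasattr(r, "__dict__") else dict(r) for r in rows]
        if not recs:
            df = pd.DataFrame(columns=_COLUMNS[table])
            if table == "patients":
                df["risk_flags"] = df["risk_flags"].astype(object)
                df["event_flags"] = df["event_flags"].astype(object)
            return df
        return pd.DataFrame.from_records(recs)

    p, o, c, r, issues = _normalize_frames(
        frame(patients, "patients"),
        frame(observations, "observations"),
        frame(conditions, "conditions"),
        frame(prescriptions, "prescriptions"),
    )
    if issues:
        raise CohortValidationError(issues)
    cohort = Cohort(p, o, c, r, pd.Timestamp(as_of))
    if validate:
        validate_cohort(cohort)
    return cohort


# ---------------------------------------------------------------------------
# I/O

def _resolve_paths(paths) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        d = Path(paths)
        out = {}
        for t in _TABLES:
            csv, jsonl = d / f"{t}.csv", d / f"{t}.jsonl"
            out[t] = csv if csv.exists() or not jsonl.exists() else jsonl
        return out
    return {t: Path(paths[t]) for t in _TABLES}


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing cohort table: {path}")
    if path.suffix == ".jsonl":
        rows = [json.loads(line) for line in path.read_text("utf-8").splitlines() if line]
        return pd.DataFrame(rows)
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def read_cohort(paths, as_of) -> Cohort:
    """Read and validate the four tables.

    ``paths`` is either a directory containing ``patients.csv``,
    ``observations.csv``, ``conditions.csv``, ``prescriptions.csv`` (or their
    ``.jsonl`` mirrors) or a mapping table-name -> file path.
    """
    resolved = _resolve_paths(paths)
    raw = {t: _read_table(resolved[t]) for t in _TABLES}
    for t in _TABLES:
        missing = [col for col in _COLUMNS[t] if col not in raw[t].columns and len(raw[t].columns)]
        if missing and not raw[t].empty:
            raise CohortValidationError([f"{t}: missing column(s) {missing}"])
    p, o, c, r, issues = _normalize_frames(
        raw["patients"], raw["observations"], raw["conditions"], raw["prescriptions"]
    )
    if issues:
        raise CohortValidationError(issues)
    cohort = Cohort(p, o, c, r, pd.Timestamp(as_of))
    validate_cohort(cohort)
    return cohort


def _fmt_num(v: float) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def _serial_frames(cohort: Cohort) -> dict[str, pd.DataFrame]:
    p = cohort.patients.copy()
    p["birth_date"] = p["birth_date"].dt.strftime("%Y-%m-%d")
    p["risk_flags"] = p["risk_flags"].map(lambda s: "|".join(sorted(s)))
    p["event_flags"] = p["event_flags"].map(lambda s: "|".join(sorted(s)))
    p["enrolled"] = p["enrolled"].map(lambda b: "true" if b else "false")
    p["consent"] = p["consent"].map(lambda b: "true" if b else "false")
    p = p.sort_values("patient_id", kind="stable")

    o = cohort.observations.copy()
    o = o.sort_values(["patient_id", "date", "code"], kind="stable")
    o["value"] = o["value"].map(_fmt_num)
    o["date"] = o["date"].dt.strftime("%Y-%m-%d")

    c = cohort.conditions.copy()
    c = c.sort_values(["patient_id", "onset_date", "condition"], kind="stable")
    c["onset_date"] = c["onset_date"].dt.strftime("%Y-%m-%d")

    r = cohort.prescriptions.copy()
    r = r.sort_values(["patient_id", "date", "drug_class"], kind="stable")
    r["date"] = r["date"].dt.strftime("%Y-%m-%d")

    return {"patients": p, "observations": o, "conditions": c, "prescriptions": r}


def write_cohort(cohort: Cohort, paths, fmt: str = "csv") -> None:
    """Write the cohort in canonical form (sorted rows, ISO dates, UTF-8, LF)."""
    if isinstance(paths, (str, Path)):
        d = Path(paths)
        d.mkdir(parents=True, exist_ok=True)
        paths = {t: d / f"{t}.{fmt}" for t in _TABLES}
    frames = _serial_frames(cohort)
    for t in _TABLES:
        path = Path(paths[t])
        df = frames[t][_COLUMNS[t]]
        if path.suffix == ".jsonl":
            with open(path, "w", encoding="utf-8") as fh:
                for rec in df.to_dict("records"):
                    fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
        else:
            df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# Temporal queries

def in_window(dates, as_of, window_days: int | None) -> pd.Series:
    """Vectorized membership in the lookback window ending at ``as_of``.

    A date exactly ``window_days`` before ``as_of`` is inside; ``window_days``
    of ``None`` means "ever" (any date <= as_of)."""
    as_of = pd.Timestamp(as_of)
    delta = (as_of - pd.to_datetime(dates)).dt.days
    if window_days is None:
        return delta >= 0
    return (delta >= 0) & (delta <= window_days)


def age_years(birth_date, as_of) -> int:
    """Completed years of age at ``as_of``."""
    b, a = pd.Timestamp(birth_date), pd.Timestamp(as_of)
    years = a.year - b.year
    if (a.month, a.day) < (b.month, b.day):
        years -= 1
    return years


def _filtered(cohort: Cohort, codes, window_days) -> pd.DataFrame:
    o = cohort.observations
    if isinstance(codes, str):
        m = o["code"] == codes
    else:
        m = o["code"].isin(list(codes))
    m &= in_window(o["date"], cohort.as_of, window_days)
    return o[m]


def latest_per_patient(
    cohort: Cohort, code, window_days: int | None = None
) -> pd.Series:
    """Most recent value of ``code`` per patient (same-date ties: last row in
    file order wins).  Returns a Series indexed by patient_id; patients with no
    qualifying observation are absent."""
    sub = _filtered(cohort, code, window_days)
    if sub.empty:
        return pd.Series(dtype=float)
    sub = sub.assign(_ord=sub.index).sort_values(["date", "_ord"], kind="stable")
    return sub.groupby("patient_id")["value"].last()


def patients_with_obs(
    cohort: Cohort, codes, window_days: int | None = None
) -> set[str]:
    """Set of patient ids with at least one observation of ``codes`` in window."""
    return set(_filtered(cohort, codes, window_days)["patient_id"])


def latest_value(
    cohort: Cohort, patient_id: str, code: str, window_days: int | None = None
) -> float | None:
    """Most recent observation value for one patient, or ``None`` if absent.

    With ``window_days`` given, only observations inside the lookback window
    ending at ``cohort.as_of`` qualify (the day-``window_days`` boundary is
    inside).  Unknown patients raise ``KeyError``; unknown codes ``ValueError``.
    """
    if code not in OBSERVATION_CODES:
        raise ValueError(f"unknown observation code {code!r}")
    if patient_id not in set(cohort.patients["patient_id"]):
        raise KeyError(f"unknown patient {patient_id!r}")
    series = latest_per_patient(cohort, code, window_days)
    if patient_id in series.index:
        return float(series.loc[patient_id])
    return None
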
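"""Ordinal care-quality labels and the random-forest quality classifier.

Chronic care quality is rated on a 5-point ordinal scale, from 1
(Excellent) to 5 (Poor).  Multiple expert raters are reconciled by
majority vote; ties are broken pessimistically, toward the worse-quality
(larger) value, so a split opinion never inflates the recorded quality.

The classifier is a random forest (Gini splitting) over the per-patient
indicator feature set: latest HbA1c, LDL and blood-pressure values,
latest BMI and waist, recency flags for microalbuminuria and creatinine,
hypertension status, and the follow-up phase.  Missing numeric values
are encoded with a sentinel plus an explicit missingness flag column —
missingness is itself informative, so no imputation is performed.

Evaluation follows a nested cross-validation protocol: a 10-fold outer
loop stratified by follow-up phase estimates generalisation accuracy and
macro-recall; inside each outer training set a 5-fold grid search picks
the forest hyperparameters (number of trees, maximum leaf count,
features per split) by macro-recall.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .ehr_core import WINDOW_DAYS, Cohort, latest_per_patient, patients_with_obs

__all__ = [
    "LIKERT_LEVELS",
    "AnnotationSet",
    "QualityDataset",
    "ClassifierConfig",
    "ClassifierReport",
    "aggregate_labels",
    "rule_scores",
    "rule_labels_from_scores",
    "build_feature_matrix",
    "build_quality_dataset",
    "nested_cv_evaluate",
    "report_metrics",
]

LIKERT_LEVELS = (1, 2, 3, 4, 5)  # 1 Excellent ... 5 Poor

MISSING_SENTINEL = -1.0


@dataclass(frozen=True)
class AnnotationSet:
    patient_id: str
    ratings: tuple[int, ...]

    @property
    def n_raters(self) -> int:
        return len(self.ratings)


def aggregate_labels(annotations: AnnotationSet | list[int]) -> int:
    """Majority-vote rating; ties resolve to the larger (worse) value."""
    ratings = annotations.ratings if isinstance(annotations, AnnotationSet) else annotations
    if not ratings:
        raise ValueError("cannot aggregate an empty rating list")
    bad = [r for r in ratings if r not in LIKERT_LEVELS]
    if bad:
        raise ValueError(f"ratings must be in 1..5, got {bad}")
    counts = Counter(ratings)
    top = max(counts.values())
    return max(r for r, c in counts.items() if c == top)


# ---------------------------------------------------------------------------
# Per-patient indicator criteria & feature matrix

def rule_scores(cohort: Cohort) -> pd.DataFrame:
    """Seven per-patient care-quality criteria plus their sum (``score``).

    Criteria (one point each, for every enrolled T2D patient): latest HbA1c
    <= 6.5 %; latest LDL <= 130 mg/dl; blood pressure at target (<= 130/80)
    if hypertensive (vacuously met otherwise); BMI recorded; waist recorded;
    microalbuminuria recorded in the last year; creatinine recorded in the
    last year.
    """
    from .indicators import AP_TARGET, HBA1C_TARGET_PCT, LDL_TARGET_MGDL, enrolled_t2d_panel

    pids = [
        pid
        for gp in sorted(set(cohort.patients["gp_id"]))
        for pid in enrolled_t2d_panel(cohort, gp)
    ]
    hba1c = latest_per_patient(cohort, "HBA1C_PCT")
    ldl = latest_per_patient(cohort, "LDL_MGDL")
    sys = latest_per_patient(cohort, "AP_SYS_MMHG")
    dia = latest_per_patient(cohort, "AP_DIA_MMHG")
    hyp = cohort.has_condition("HYPERTENSION")
    bmi = patients_with_obs(cohort, "BMI_KGM2")
    waist = patients_with_obs(cohort, "WAIST_CM")
    micro = patients_with_obs(cohort, "MICROALBUMINURIA_MGL", WINDOW_DAYS)
    creat = patients_with_obs(cohort, "CREATININE_MGDL", WINDOW_DAYS)

    rows = {}
    for pid in pids:
        ap_ok = (
            pid not in hyp
            or (
                pid in sys.index
                and pid in dia.index
                and sys[pid] <= AP_TARGET[0]
                and dia[pid] <= AP_TARGET[1]
            )
        )
        crit = {
            "hba1c_at_target": pid in hba1c.index and hba1c[pid] <= HBA1C_TARGET_PCT,
            "ldl_at_target": pid in ldl.index and ldl[pid] <= LDL_TARGET_MGDL,
            "ap_at_target_if_hypertensive": ap_ok,
            "bmi_recorded": pid in bmi,
            "waist_recorded": pid in waist,
            "microalbuminuria_recent": pid in micro,
            "creatinine_recent": pid in creat,
        }
        crit["score"] = sum(bool(v) for k, v in crit.items())
        rows[pid] = crit
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df


#: Monotone map from criteria-met count (0..7) to the Likert label.
SCORE_TO_LABEL = {7: 1, 6: 2, 5: 3, 4: 4}


def rule_labels_from_scores(scores: pd.Series) -> pd.Series:
    """Map criteria counts to Likert labels (7 met -> 1 Excellent, ...,
    <= 3 met -> 5 Poor)."""
    return scores.map(lambda s: SCORE_TO_LABEL.get(int(s), 5)).astype(int)


def build_feature_matrix(
    cohort: Cohort, *, include_raw_values: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-patient indicator feature set for every enrolled T2D patient.

    Returns ``(features, phases)``.  The default feature set is the
    per-patient *indicator status view* — the machine encoding of what a
    rater sees on the patient sheet: one binary at-target/recorded status
    per indicator criterion, a missingness (grey-cell) flag per underlying
    measurement, hypertension status and a one-hot of the follow-up phase.
    With ``include_raw_values`` the latest raw laboratory values are
    appended (``-1`` sentinel when absent); the statuses already summarise
    them, so this is off by default.
    """
    from .followup import PHASES, phases_for
    from .indicators import enrolled_t2d_panel

    pids = [
        pid
        for gp in sorted(set(cohort.patients["gp_id"]))
        for pid in enrolled_t2d_panel(cohort, gp)
    ]
    latest = {
        "hba1c_latest": latest_per_patient(cohort, "HBA1C_PCT"),
        "ldl_latest": latest_per_patient(cohort, "LDL_MGDL"),
        "ap_sys_latest": latest_per_patient(cohort, "AP_SYS_MMHG"),
        "ap_dia_latest": latest_per_patient(cohort, "AP_DIA_MMHG"),
        "bmi_latest": latest_per_patient(cohort, "BMI_KGM2"),
        "waist_latest": latest_per_patient(cohort, "WAIST_CM"),
    }
    hyp = cohort.has_condition("HYPERTENSION")
    phases = phases_for(cohort, pids)
    statuses = rule_scores(cohort).drop(columns="score").loc[pids]

    data: dict[str, list[float]] = {
        col: statuses[col].astype(float).tolist() for col in statuses.columns
    }
    for name, series in latest.items():
        data[f"{name}_missing"] = [float(pid not in series.index) for pid in pids]
        if include_raw_values:
            data[name] = [float(series.get(pid, MISSING_SENTINEL)) for pid in pids]
    data["hypertensive"] = [float(pid in hyp) for pid in pids]
    for ph in PHASES:
        data[f"phase_{ph}"] = [float(phases[pid] == ph) for pid in pids]

    features = pd.DataFrame(data, index=pd.Index(pids, name="patient_id"))
    return features, phases.loc[pids]


@dataclass
class QualityDataset:
    """Feature matrix, ordinal labels and follow-up phase per patient."""

    features: pd.DataFrame
    labels: pd.Series
    phases: pd.Series

    def __post_init__(self):
        if not (self.features.index.equals(self.labels.index) and
                self.features.index.equals(self.phases.index)):
            raise ValueError("features, labels and phases must share an index")
        if self.features.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")
        bad = set(self.labels.unique()) - set(LIKERT_LEVELS)
        if bad:
            raise ValueError(f"labels must be in 1..5, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


def build_quality_dataset(cohort: Cohort, labels: pd.Series) -> QualityDataset:
    """Assemble a dataset from a cohort and per-patient ordinal labels."""
    features, phases = build_feature_matrix(cohort)
    labels = labels.reindex(features.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:3]
        raise ValueError(f"labels missing for enrolled patients, e.g. {missing}")
    return QualityDataset(features, labels.astype(int), phases)


# ---------------------------------------------------------------------------
# Nested cross-validation

class ClassifierConfig(BaseModel):
    """Random-forest grid and nested-CV protocol parameters."""

    n_trees: list[int] = Field(default=[50, 100, 200])
    max_splits: list[int] = Field(default=[8, 32, 128])
    n_features_per_split: list[object] = Field(default=["sqrt", 0.333, 1.0])
    outer_folds: int = 10
    inner_folds: int = 5
    seed: int = 0

    @field_validator("n_trees", "max_splits", "n_features_per_split")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("hyperparameter grids must be non-empty")
        return v

    @field_validator("outer_folds", "inner_folds")
    @classmethod
    def _folds(cls, v):
        if v < 2:
            raise ValueError("folds must be >= 2")
        return v


@dataclass
class ClassifierReport:
    fold_accuracy: list[float]
    fold_macro_recall: list[float]
    fold_params: list[dict]
    confusion: pd.DataFrame  # pooled over outer test folds; rows true, cols predicted

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy))

    @property
    def mean_macro_recall(self) -> float:
        return float(np.mean(self.fold_macro_recall))

    @property
    def std_macro_recall(self) -> float:
        return float(np.std(self.fold_macro_recall))

    def to_dict(self) -> dict:
        return {
            "fold_accuracy": self.fold_accuracy,
            "fold_macro_recall": self.fold_macro_recall,
            "fold_params": self.fold_params,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "mean_macro_recall": self.mean_macro_recall,
            "std_macro_recall": self.std_macro_recall,
            "confusion": {
                "labels": [int(x) for x in self.confusion.index],
                "matrix": self.confusion.to_numpy().tolist(),
            },
        }


def report_metrics(confusion) -> tuple[float, float]:
    """(overall accuracy, macro-recall) from a square confusion matrix
    (rows = true class, columns = predicted class).

    Classes with zero support are excluded from the macro average with a
    warning."""
    m = np.asarray(confusion, dtype=float)
    if m.size == 0 or m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square and non-empty")
    total = m.sum()
    if total == 0:
        raise ValueError("confusion matrix has no observations")
    accuracy = float(np.trace(m) / total)
    support = m.sum(axis=1)
    present = support > 0
    if not present.all():
        warnings.warn(
            f"{int((~present).sum())} class(es) with zero support excluded "
            "from the macro-recall average",
            stacklevel=2,
        )
    recalls = np.diag(m)[present] / support[present]
    return accuracy, float(recalls.mean())


def _grid(config: ClassifierConfig, n_features: int) -> dict:
    feats = []
    for f in config.n_features_per_split:
        if f == "sqrt":
            feats.append("sqrt")
        elif isinstance(f, (int, np.integer)):
            feats.append(int(f))
        else:
            feats.append(max(1, int(round(float(f) * n_features))))
    return {
        "n_estimators": list(config.n_trees),
        "max_leaf_nodes": list(config.max_splits),
        "max_features": feats,
    }


def nested_cv_evaluate(dataset: QualityDataset, config: ClassifierConfig) -> ClassifierReport:
    """Nested cross-validated evaluation of the random-forest classifier.

    The outer ``config.outer_folds``-fold split is stratified by follow-up
    phase; the inner ``config.inner_folds``-fold grid search maximises
    macro-recall.  Fully reproducible given ``config.seed``.
    """
    y = dataset.labels.to_numpy()
    X = dataset.features.to_numpy(dtype=float)
    phases = dataset.phases.to_numpy()

    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("dataset must contain at least two quality classes")
    strata, counts = np.unique(phases, return_counts=True)
    small = [f"{s} (n={c})" for s, c in zip(strata, counts) if c < config.outer_folds]
    if small:
        raise ValueError(
            f"phase stratum too small for {config.outer_folds}-fold CV: {', '.join(small)}"
        )

    outer = StratifiedKFold(
        n_splits=config.outer_folds, shuffle=True, random_state=config.seed
    )
    all_labels = list(LIKERT_LEVELS)
    pooled = np.zeros((len(all_labels), len(all_labels)), dtype=int)
    accs, mrecs, params = [], [], []

    for k, (tr, te) in enumerate(outer.split(X, phases)):
        rf = RandomForestClassifier(criterion="gini", random_state=config.seed + k)
        search = GridSearchCV(
            rf,
            _grid(config, X.shape[1]),
            scoring="recall_macro",
            cv=StratifiedKFold(
                n_splits=config.inner_folds, shuffle=True, random_state=config.seed + k
            ),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # folds may miss rare classes
            search.fit(X[tr], y[tr])
            pred = search.best_estimator_.predict(X[te])
        fold_conf = np.zeros_like(pooled)
        for t, p in zip(y[te], pred):
            fold_conf[all_labels.index(t), all_labels.index(p)] += 1
        pooled += fold_conf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc, mrec = report_metrics(fold_conf)
        accs.append(acc)
        mrecs.append(mrec)
        params.append(dict(search.best_params_))

    confusion = pd.DataFrame(pooled, index=all_labels, columns=all_labels)
    return ClassifierReport(accs, mrecs, params, confusion)
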
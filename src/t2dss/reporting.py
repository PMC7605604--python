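"""End-to-end pipeline driver and human-readable reporting.

``run_all`` executes the full decision-support pipeline on a cohort
directory — enrollment proposals, screening, care-quality indicators,
incentive statements, follow-up routing, optionally the quality
classifier — writing one machine-readable output per stage plus a run
manifest.  ``render_report`` turns a manifest into a markdown + JSON
consultation report: per-GP indicator tables (Ratio / Target / Distance /
LAP / Mean), a per-patient flag table with OK / WARN / MISSING states
(the machine encoding of the green / red / grey cells GPs see), and the
incentive summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrollment as enrollment_mod
from . import followup as followup_mod
from . import incentives as incentives_mod
from . import indicators as indicators_mod
from . import screening as screening_mod
from .ehr_core import Cohort, WINDOW_DAYS, latest_value, patients_with_obs, read_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "StageError", "run_all", "render_report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    as_of: str
    seed: int
    cohort_dir: str
    outputs: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), "utf-8")


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError(name, exc) from exc
            logger.info("stage %s: %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("enroll")
def _run_enroll(cohort: Cohort, out: Path) -> int:
    decisions = enrollment_mod.propose_enrollment(cohort)
    df = pd.DataFrame(
        [
            {"patient_id": d.patient_id, "action": d.action, "reasons": "|".join(d.reasons)}
            for d in decisions
        ],
        columns=["patient_id", "action", "reasons"],
    )
    df.to_csv(out, index=False, lineterminator="\n")
    return len(df)


@_stage("screen")
def _run_screen(cohort: Cohort, out: Path) -> int:
    results = screening_mod.screen_cohort(cohort)
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "eligible": r.eligible,
                "eligibility_reasons": "|".join(r.eligibility_reasons),
                "glycemic_class": r.glycemic_class,
                "next_screen_due": "" if r.next_screen_due is None
                else r.next_screen_due.strftime("%Y-%m-%d"),
            }
            for r in results
        ],
        columns=["patient_id", "eligible", "eligibility_reasons", "glycemic_class",
                 "next_screen_due"],
    )
    df.to_csv(out, index=False, lineterminator="\n")
    return len(df)


@_stage("indicators")
def _run_indicators(cohort: Cohort, targets_path: Path | None, out: Path) -> int:
    targets = indicators_mod.load_targets(targets_path) if targets_path else None
    registry = indicators_mod.default_registry(targets)
    per_gp = indicators_mod.compute_all(cohort, registry)
    payload = {
        "as_of": cohort.as_of.strftime("%Y-%m-%d"),
        "gps": {
            gp: {
                "indicators": [
                    {
                        "indicator_id": r.indicator_id,
                        "name": registry[r.indicator_id].name,
                        "numerator": r.numerator,
                        "denominator": r.denominator,
                        "ratio": r.ratio,
                        "target": r.target,
                        "distance": r.distance,
                        "lap_awarded": r.lap_awarded,
                        "project_mean": r.project_mean,
                        "missing": r.empty_denominator,
                    }
                    for r in results
                ],
                "drug_usage": indicators_mod.drug_usage(cohort, gp),
                "complications_in_act": indicators_mod.complications_in_act(cohort, gp),
                "self_audit": indicators_mod.self_audit(cohort, gp, registry=registry),
            }
            for gp, results in per_gp.items()
        },
        "max_lap": sum(d.lap_points for d in registry.values()),
    }
    out.write_text(json.dumps(payload, indent=2), "utf-8")
    return len(per_gp)


@_stage("score")
def _run_score(cohort: Cohort, indicators_path: Path, tiers_path: Path | None, out: Path) -> int:
    data = json.loads(indicators_path.read_text("utf-8"))
    tiers = incentives_mod.load_tiers(tiers_path) if tiers_path else incentives_mod.DEFAULT_TIERS
    max_lap = float(data["max_lap"])
    statements = []
    for gp, block in data["gps"].items():
        score = sum(i["lap_awarded"] for i in block["indicators"])
        n_enrolled = len(indicators_mod.enrolled_t2d_panel(cohort, gp))
        st = incentives_mod.incentive_statement(gp, n_enrolled, score, max_lap, tiers)
        statements.append(st.__dict__)
    out.write_text(json.dumps({"statements": statements}, indent=2), "utf-8")
    return len(statements)


@_stage("route")
def _run_route(cohort: Cohort, out: Path) -> int:
    assignments = followup_mod.route_cohort(cohort)
    payload = [
        {
            "patient_id": a.patient_id,
            "phase": a.phase,
            "due_actions": [
                {"action": name, "due": d.strftime("%Y-%m-%d")} for name, d in a.due_actions
            ],
            "referral": a.referral,
            "referral_reasons": list(a.referral_reasons),
        }
        for a in assignments
    ]
    out.write_text(json.dumps(payload, indent=2), "utf-8")
    return len(payload)


@_stage("train-quality")
def _run_quality(cohort: Cohort, seed: int, out: Path) -> int:
    from .quality_model import ClassifierConfig, nested_cv_evaluate
    from .synthetic_cohort import generate_quality_labels

    dataset = generate_quality_labels(cohort, rule_noise=0.1, seed=seed)
    config = ClassifierConfig(
        n_trees=[100], max_splits=[64], n_features_per_split=["sqrt"], seed=seed
    )
    report = nested_cv_evaluate(dataset, config)
    out.write_text(json.dumps(report.to_dict(), indent=2), "utf-8")
    return len(dataset)


def run_all(
    cohort_dir,
    config_dir,
    as_of,
    seed: int = 0,
    out_dir=None,
    *,
    train_quality: bool = False,
) -> RunManifest:
    """Run every pipeline stage; outputs land in ``out_dir`` and the manifest
    is written last.  ``config_dir`` must contain ``targets.yaml`` (indicator
    targets); ``tiers.yaml`` (LAP tier schedule) is optional."""
    cohort_dir, config_dir = Path(cohort_dir), Path(config_dir)
    out_dir = Path(out_dir) if out_dir else cohort_dir / "out"
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(cohort_dir, as_of)
    manifest = RunManifest(
        as_of=pd.Timestamp(as_of).strftime("%Y-%m-%d"),
        seed=seed,
        cohort_dir=str(cohort_dir),
    )
    manifest.row_counts["patients"] = len(cohort.patients)

    targets_path = config_dir / "targets.yaml"
    if not targets_path.exists():
        raise StageError("indicators", FileNotFoundError(f"missing {targets_path}"))
    tiers_path = config_dir / "tiers.yaml"

    stages: list[tuple[str, Path, int]] = []
    p = out_dir / "enrollment.csv"
    stages.append(("enrollment", p, _run_enroll(cohort, p)))
    p = out_dir / "screening.csv"
    stages.append(("screening", p, _run_screen(cohort, p)))
    p = out_dir / "indicators.json"
    stages.append(("indicators", p, _run_indicators(cohort, targets_path, p)))
    p = out_dir / "incentives.json"
    stages.append(
        ("incentives", p, _run_score(cohort, out_dir / "indicators.json",
                                     tiers_path if tiers_path.exists() else None, p))
    )
    p = out_dir / "followup.json"
    stages.append(("followup", p, _run_route(cohort, p)))
    if train_quality:
        p = out_dir / "quality_report.json"
        stages.append(("quality", p, _run_quality(cohort, seed, p)))

    for name, path, count in stages:
        manifest.outputs[name] = str(path)
        manifest.row_counts[name] = count
    manifest.save(out_dir / "manifest.json")
    manifest.outputs["manifest"] = str(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Reporting

_FLAG_FIELDS = (
    ("HbA1c", ("HBA1C_PCT",), "threshold"),
    ("LDL", ("LDL_MGDL",), "threshold"),
    ("AP", ("AP_SYS_MMHG", "AP_DIA_MMHG"), "threshold"),
    ("BMI", ("BMI_KGM2",), "recorded"),
    ("Waist", ("WAIST_CM",), "recorded"),
    ("Microalbuminuria", ("MICROALBUMINURIA_MGL",), "recorded_window"),
    ("Creatinine", ("CREATININE_MGDL",), "recorded_window"),
)


def patient_flags(cohort: Cohort, patient_id: str) -> dict[str, str]:
    """Per-field OK / WARN / MISSING states for one patient.

    Threshold fields (HbA1c <= 6.5, LDL <= 130, AP <= 130/80) are OK when
    within target, WARN when out of range, MISSING when never recorded;
    recording fields are OK when a coherent numeric value exists in their
    window, MISSING otherwise."""
    from .indicators import AP_TARGET, HBA1C_TARGET_PCT, LDL_TARGET_MGDL

    out: dict[str, str] = {}
    for name, codes, kind in _FLAG_FIELDS:
        if kind == "threshold":
            values = [latest_value(cohort, patient_id, c) for c in codes]
            if any(v is None for v in values):
                out[name] = "MISSING"
                continue
            if name == "HbA1c":
                ok = values[0] <= HBA1C_TARGET_PCT
            elif name == "LDL":
                ok = values[0] <= LDL_TARGET_MGDL
            else:
                ok = values[0] <= AP_TARGET[0] and values[1] <= AP_TARGET[1]
            out[name] = "OK" if ok else "WARN"
        else:
            window = WINDOW_DAYS if kind == "recorded_window" else None
            present = patient_id in patients_with_obs(cohort, codes, window)
            out[name] = "OK" if present else "MISSING"
    return out


def render_report(manifest: RunManifest, cohort: Cohort | None = None) -> tuple[str, dict]:
    """Render a manifest's outputs as (markdown, JSON-safe dict)."""
    ind = json.loads(Path(manifest.outputs["indicators"]).read_text("utf-8"))
    inc = json.loads(Path(manifest.outputs["incentives"]).read_text("utf-8"))
    if cohort is None:
        cohort = read_cohort(manifest.cohort_dir, manifest.as_of)

    from .indicators import enrolled_t2d_panel

    patient_table = {}
    for gp in sorted(ind["gps"]):
        for pid in enrolled_t2d_panel(cohort, gp):
            patient_table[pid] = {"gp_id": gp, **patient_flags(cohort, pid)}

    report = {
        "as_of": ind["as_of"],
        "indicators": ind["gps"],
        "incentives": inc["statements"],
        "patients": patient_table,
    }

    lines = [f"# Integrated-management report — as of {ind['as_of']}", ""]
    for gp in sorted(ind["gps"]):
        lines += [f"## GP {gp}", "",
                  "| Indicator | Ratio | Target | Distance | LAP | Mean |",
                  "|---|---|---|---|---|---|"]
        for r in ind["gps"][gp]["indicators"]:
            mean = "-" if r["project_mean"] is None else f"{r['project_mean']:.3f}"
            lines.append(
                f"| {r['indicator_id']} {r['name']} | {r['ratio']:.3f} | "
                f"{r['target']:.2f} | {r['distance']:+.3f} | {r['lap_awarded']:g} | {mean} |"
            )
        lines.append("")
    lines += ["## Incentives", "",
              "| GP | Enrolled | Base (EUR) | LAP score | Tier (EUR/pt/yr) | Total (EUR) |",
              "|---|---|---|---|---|---|"]
    for st in inc["statements"]:
        lines.append(
            f"| {st['gp_id']} | {st['n_enrolled']} | {st['base_pay']:g} | "
            f"{st['lap_score']:g} | {st['lap_tier_rate']:g} | {st['total']:g} |"
        )
    lines.append("")
    if patient_table:
        cols = [f[0] for f in _FLAG_FIELDS]
        lines += ["## Patient flags", "",
                  "| Patient | GP | " + " | ".join(cols) + " |",
                  "|" + "---|" * (len(cols) + 2)]
        for pid in sorted(patient_table):
            row = patient_table[pid]
            lines.append(
                f"| {pid} | {row['gp_id']} | " + " | ".join(row[c] for c in cols) + " |"
            )
        lines.append("")
    return "\n".join(lines), report
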
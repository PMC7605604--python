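# t2dss — decision support for GP-led Type 2 Diabetes chronic care

`t2dss` is a tested, reusable implementation of an integrated-management
decision support system for Type 2 Diabetes (T2D) in primary care.  It is
aimed at clinical-informatics researchers and health-system analysts who
need the *rules* of a chronic-care programme — enrollment, screening,
follow-up routing, care-quality measurement, pay-for-performance scoring —
as executable, auditable code rather than prose, together with a synthetic
GP-panel generator that makes every stage testable without patient data.

## What it computes

Given a GP panel as four flat EHR tables (patients, coded dated
observations, conditions, prescriptions) and an evaluation date:

* **Enrollment** (`t2dss.enrollment`) — proposes every T2D patient for the
  programme unless a major complication is on record (CHD, ictus,
  peripheral arterial disease, retinopathy), any HbA1c in the last year
  exceeds 8 % or insulin was prescribed in the last year; flags probable
  undiagnosed diabetics as advisory "potential" additions.
* **Screening** (`t2dss.screening`) — fasting-glucose screening
  eligibility (age ≥ 45, or BMI > 25 kg/m² plus a risk condition under
  45) and glycemic classification with the standard bands: IFG at fasting
  glucose 100–125 mg/dl, IGT at 2h-OGTT 140–199, diabetes at FPG ≥ 126 or
  OGTT ≥ 200, an HbA1c 42–48 mmol/mol risk band; 3-yearly re-screening,
  accelerated under dysglycemia.
* **Care-quality indicators** (`t2dss.indicators`) — eleven per-GP
  numerator/denominator ratios.  For an indicator with numerator rule
  *q* over a panel *D*, the GP's ratio, distance and award are

      ratio = |{p ∈ D : q(p)}| / |D|,   distance = ratio − target,
      LAP points awarded  ⇔  ratio ≥ target

  with 12-month lookback windows for the process indicators, latest-value
  thresholds for the outcome indicators (HbA1c ≤ 6.5 %, LDL ≤ 130 mg/dl,
  AP ≤ 130/80 mmHg among hypertensive diabetics), and the lipid-profile
  computability rule (latest triglycerides > 200 mg/dl removes a patient
  from numerator and denominator alike).
* **Incentives** (`t2dss.incentives`) — 50 € per enrolled patient base
  remuneration plus a tiered LAP bonus of 30/40/50 € per patient/year
  driven by the summed LAP score.
* **Follow-up routing** (`t2dss.followup`) — phases A/B plus the annual
  center review, due-action scheduling (quarterly visit, annual labs,
  2-yearly fundus oculi, 6-monthly center review in B) and urgent vs
  programmable specialist-referral triggers (repeated FPG > 180 mg/dl,
  HbA1c > 6.5 % twice, new complication; acute events are urgent).
* **Care-quality classifier** (`t2dss.quality_model`) — 5-level ordinal
  quality labels (1 Excellent … 5 Poor), majority-vote aggregation of
  multi-rater annotations with pessimistic ties, and a Gini random forest
  over the per-patient indicator-status view, evaluated by 10-fold
  phase-stratified nested cross-validation with an inner 5-fold grid
  search maximising macro-recall.
* **Synthetic cohorts** (`t2dss.synthetic_cohort`) — seeded,
  byte-reproducible GP panels with configurable prevalence, complication
  rates, lab schedules, missingness and value distributions, plus
  rule-generated quality labels with controllable noise.

See `docs/methods.md` for the full conventions (window semantics, boundary
strictness, reconstructions) and limitations.

## Worked example

Generate a 2 000-patient panel, write the default indicator targets, and
run the whole pipeline:

```bash
t2dss generate --out cohort --seed 7
python -c "
import yaml
from t2dss.indicators import DEFAULT_TARGETS
payload = {i: {'target': t, 'lap_points': p} for i, (t, p) in DEFAULT_TARGETS.items()}
open('config/targets.yaml', 'w').write(yaml.safe_dump(payload))
"
t2dss run-all --cohort cohort --config config --as-of 2019-12-31 --seed 7 --out out
```

`out/report.md` then opens with one table per GP:

```
| Indicator | Ratio | Target | Distance | LAP | Mean |
|---|---|---|---|---|---|
| 1.1 T2D patients among all assisted | 0.066 | 0.06 | +0.006 | 5 | 0.078 |
| 2.1 Diabetics with annual HbA1c | 0.923 | 0.80 | +0.123 | 10 | 0.800 |
| 2.2 Diabetics with annual lipid profile | 0.625 | 0.60 | +0.025 | 10 | 0.328 |
| 2.3 Diabetics with annual AP | 1.000 | 0.80 | +0.200 | 10 | 0.965 |
| ...
| 3.1 Diabetics with HbA1c <= 6.5% | 0.462 | 0.25 | +0.212 | 15 | 0.254 |
```

Reading the first row: 6.6 % of GP G001's assisted patients carry a T2D
diagnosis, above the 6 % project target, so the indicator's 5 LAP points
are awarded; the project-wide mean across GPs is 7.8 %.  The per-GP
incentive statement in `out/incentives.json` applies the tier schedule to
the summed LAP score:

```json
{
  "gp_id": "G001",
  "n_enrolled": 13,
  "base_pay": 650.0,
  "lap_score": 60.0,
  "lap_tier_rate": 30.0,
  "lap_pay": 390.0,
  "total": 1040.0
}
```

G001 enrolled 13 diabetics (13 × 50 € = 650 € base pay) and reached 60 of
110 attainable LAP points — past the 50 % tier, so a 30 €/patient/year
bonus (390 €) brings the total to 1 040 €.  `out/followup.json` and
`out/screening.csv` carry the per-patient routing and screening decisions,
and `out/report.md` ends with the per-patient OK/WARN/MISSING flag table.

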
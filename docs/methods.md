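# Methods

This note documents the models, rules and numerical conventions behind
`t2dss`, the design choices made where the problem was genuinely open, and
what the synthetic-cohort experiments do and do not demonstrate.

## The decision-support pipeline

The package implements an integrated-management programme for Type 2
Diabetes (T2D) in primary care.  A GP's panel is represented as four flat
tables (patients, coded observations, conditions, prescriptions) evaluated
at a single `as_of` date.  Five rule engines and one statistical model run
on top of that data model:

1. **Enrollment** — T2D patients are proposed for the programme unless a
   major complication (coronary heart disease, ictus, peripheral arterial
   disease, retinopathy) is on record, any HbA1c observation in the last
   year exceeds 8 % (uncompensated diabetes), or insulin was prescribed in
   the last year.  Non-T2D patients on oral antidiabetics or with repeated
   glycemic checks are flagged as *potential* T2D; this is advisory — the
   GP always takes the final decision, and the thresholds (≥ 2 in-window
   checks) are configurable because the underlying criterion is stated
   qualitatively, not as a formula.
2. **Screening** — fasting plasma glucose (FPG) screening for everyone
   aged ≥ 45, and for under-45s with BMI > 25 kg/m² plus at least one risk
   condition.  Glycemic classification: DIABETES at FPG ≥ 126 mg/dl or
   2h-OGTT ≥ 200; IGT at OGTT 140–199; IFG at FPG 100–125; an HbA1c risk
   band at 42–48 mmol/mol; re-screening every 3 years, yearly (default,
   configurable) under dysglycemia.
3. **Indicators** — eleven numerator/denominator care-quality ratios per
   GP (prevalence correspondence; seven process indicators; three outcome
   indicators: latest HbA1c ≤ 6.5 %, latest LDL ≤ 130 mg/dl, latest blood
   pressure ≤ 130/80 mmHg among hypertensive diabetics).  The lipid-profile
   indicator is not computable for patients whose latest triglycerides
   exceed 200 mg/dl; they leave numerator *and* denominator together.
4. **Incentives** — 50 € per enrolled patient base pay, plus a LAP
   ("Acceptable Level of Performance") bonus of 30/40/50 € per patient per
   year.  An indicator's LAP points are awarded when its ratio reaches or
   exceeds the project target (the inclusive reading; configurable).
5. **Follow-up routing** — phase A (uncomplicated: quarterly GP visit,
   annual lab panel, fundus oculi every 2 years), phase B (complications,
   insulin, or HbA1c > 8 % in-window: additionally a 6-monthly
   diabetes-center review), an annual center screening for every diabetic,
   plus referral triggers: *urgent* on acute events (foot ulcer, severe
   hypoglycemia, pregnancy, metabolic instability), *programmable* on
   repeated FPG > 180 mg/dl, two consecutive HbA1c > 6.5 %, or a newly
   recorded complication.
6. **Care-quality classifier** — a random forest over the per-patient
   indicator view, evaluated by nested cross-validation (below).

## Temporal and boundary conventions

* A "last 12 months" window is the fixed 365-day lookback
  `0 ≤ (as_of − date).days ≤ 365`: an observation dated exactly 365 days
  before `as_of` is inside, 366 days is outside.  No leap-year adjustment.
* All printed clinical thresholds are implemented as exact decision
  boundaries with their stated strictness: HbA1c exclusion strictly > 8 %;
  outcome HbA1c inclusive ≤ 6.5 %; triglyceride computability strictly
  > 200; BMI gate strictly > 25; referral FPG strictly > 180.  Where only
  one side of a boundary is stated, the complement closes it consistently:
  FPG 126 is diagnostic (because < 126 is "not diagnostic"), OGTT 200 is
  diagnostic (because IGT ends at 199).
* The dysglycemia band for accelerated re-screening follows the labelled
  IFG range 100–125 inclusive.
* Same-date duplicate observations: the last row in file order wins, with
  a logged warning (there are no intraday timestamps in the schema).
* HbA1c is handled in two units with no conversion: percent is canonical
  for every threshold rule; mmol/mol feeds only the 42–48 risk band.
* Dates are ISO-8601, files UTF-8, decimals use `.`; cohort serialization
  is canonical (sorted rows, LF endings), so writing is idempotent and
  byte-reproducible.

## Reconstructions where the workflow is under-specified

* **Diabetes-center visits** have no code in the flat observation
  vocabulary; a recorded ECG (`ECG_DONE`) is the marker of the latest
  center review (the center panel includes an ECG).  Due dates are
  last-marker + period, due immediately when never recorded, and may lie
  in the past (overdue).
* **"Two consecutive determinations"** of HbA1c means the two most recent
  values regardless of spacing; **"repeated"** fasting glucose means ≥ 2
  qualifying in-window observations (count configurable).
* **New-diagnosis horizon**: a T2D onset within 90 days of `as_of`
  (configurable) routes to the new-diagnosis phase.
* **Indicator targets and LAP points** are project configuration.  The
  shipped defaults (`t2dss.indicators.DEFAULT_TARGETS`) and the tier
  schedule (≥ 50 % of the maximum attainable LAP → 30 €, ≥ 70 % → 40 €,
  ≥ 90 % → 50 €) are explicitly synthetic placeholders; every analysis can
  supply its own YAML.

## The synthetic-cohort generator

The generator emulates a GP panel, not any real database.  Defaults:
2 000 patients across 10 GPs, ages 30–90, T2D prevalence 8 % (in line with
adult prevalence estimates for Western Europe), complication rates among
diabetics of CHD 10 %, ictus 4 %, peripheral arterial disease 5 %,
retinopathy 8 %, hypertension 50 %; insulin therapy in 15 % of diabetics;
a 90 % GP enrollment rate among diabetics.  Observation streams follow a
thinned-Poisson schedule per code over a 730-day history (e.g. HbA1c every
180 days, blood pressure every 90, microalbuminuria and creatinine yearly)
with a default 20 % missingness per scheduled measurement; values come
from per-code truncated normals (HbA1c 7.1 ± 1.1 %, LDL 128 ± 30 mg/dl,
systolic 133 ± 15 mmHg, …).  The lipid profile is drawn as one panel on
shared dates, and the diastolic reading is paired with every systolic one.
Non-diabetic patients get sparser streams with near-normal glycemia.

Generation is a pure function of `(config, seed)`; every table and code
uses its own RNG stream derived from the seed, so the output is
byte-identical across runs and configured rates are recovered within
binomial sampling error (verified at n = 5 000 within 3 standard errors).

What the generator does **not** model: disease progression, drug response,
correlations between labs and conditions beyond the group-level means, and
visit clustering.  Passing tests on synthetic panels therefore demonstrate
the correctness of the rules and the learnability of a known signal — not
clinical performance on real records.

## Care-quality labels and the classifier

**Labels.**  Care quality is an ordinal 5-level scale, 1 (Excellent) to 5
(Poor).  Multi-rater annotations are aggregated by majority vote with
*pessimistic* tie-breaking (the worse-quality value wins a tie), so a
split panel never inflates quality; a mean-then-round alternative would
hide disagreement direction and is intentionally not the default.

For testing without expert raters, the generator labels each enrolled
patient by a documented deterministic rule: count the seven per-patient
criteria met (HbA1c ≤ 6.5 %; LDL ≤ 130; pressure ≤ 130/80 if hypertensive,
vacuously met otherwise; BMI recorded; waist recorded; microalbuminuria in
window; creatinine in window) and map the count monotonically onto the
scale (7 → 1, 6 → 2, 5 → 3, 4 → 4, ≤ 3 → 5).  Label noise replaces the
rule label, with probability `rule_noise`, by a uniform draw over the full
scale — at `rule_noise` 1 the labels are independent of the features, so
the expected macro-recall is the 5-class chance level of 0.2.  (Flipping
only to the *other* four levels was considered and rejected: it leaves the
exclusion of the rule label learnable and provably caps macro-recall at
exactly 0.25, which defeats the purpose of a chance-level control.)

**Features.**  The classifier input is the per-patient indicator *status*
view — the machine encoding of the sheet a rater sees: one binary
at-target/recorded status per criterion, a missingness ("grey cell") flag
per underlying measurement, hypertension status, and a one-hot of the
follow-up phase.  Raw latest laboratory values can be appended
(`include_raw_values=True`) but are off by default: the statuses already
summarise them, and greedy axis-aligned splits on raw values generalise
poorly immediately around the clinical thresholds, which measurably hurts
rare-class recall.  Missing values are never imputed — missingness is
itself informative.

**Evaluation.**  Nested cross-validation: a 10-fold outer loop stratified
by follow-up phase estimates accuracy and macro-recall (mean ± SD across
folds, plus a pooled confusion matrix); within each outer training set a
5-fold grid search over the forest hyperparameters (number of trees,
maximum leaf count, features per split; Gini splitting) maximises
macro-recall.  Macro-recall is the unweighted mean of per-class recalls;
classes with zero support in a fold are excluded from that fold's average
with a warning.  Everything is seeded: outer folds, inner folds and each
fold's forest derive from the single configuration seed, so reports are
exactly reproducible.

The default hyperparameter grid is trees {50, 100, 200}, maximum leaves
{8, 32, 128}, features per split {√p, p/3, p}.  The acceptance experiments
use an explicit reduced grid (trees {100}, leaves {128, 256}, features
{√p, p}) at roughly 1 000 labelled patients — the package's desk-scale
problem size; the count-of-criteria rule needs up to 2⁷ leaf regions and
all criteria visible at a split, which is why the full-feature, high-leaf
corner of the grid wins.  Measured behaviour under those conditions: mean
macro-recall ≈ 0.99 at zero label noise, decaying monotonically through
intermediate noise levels to ≈ 0.18 (chance) at full noise.

## Self-audit areas

Per GP: *recording completeness* (mean fraction of the seven audited
fields recorded in their windows over the enrolled panel), *adherence to
prevalence* (absolute distance between panel T2D prevalence and a
configurable reference, default 6 %), *treatment of chronic disease* (mean
of the three outcome indicators) and *contact intensity* (observations +
prescriptions per enrolled patient over the last 365 days).  Drug-usage
and complications-in-act frequency blocks are descriptive (no LAP points).

## Known limitations

* The potential-T2D heuristic, the phase-B "stabilized complication"
  rule, the center-visit marker and the new-diagnosis horizon are
  reconstructions of a workflow that is described narratively; all are
  configurable and flagged above.
* Indicator targets, LAP points and tier boundaries ship as synthetic
  defaults, not calibrated policy values.
* The classifier experiments quantify recovery of a known labelling rule
  under controlled noise; they say nothing about agreement with human
  expert ratings on real records.
* Cardiovascular risk scoring is out of scope; clinical evidence of CVD
  enters only as a recorded risk flag.
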
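# Methods

## The linkage problem

Three routinely collected hospital tables must be joined to relate
patient outcomes to costs:

| dataset  | grain            | keys                        | dates                         |
|----------|------------------|-----------------------------|-------------------------------|
| clinical | one row/patient  | patient ID                  | diagnosis, episode, PROM      |
| service  | one row/claim    | patient ID **+ case number**| service date                  |
| cost     | one row/cost line| case number only            | billing month/year (lagging)  |

The case number is the only key shared by the service and cost datasets;
the clinical dataset knows nothing about case numbers, and the cost
dataset knows nothing about patients. Billing dates cannot be used for
windowing or linkage because billing may trail the service by months.
Linkage therefore runs clinical → (patient ID) → service → (case
number) → cost.

## Merge step 1 — the grouped dataset

*Cohort.* The full analysis set (FAS) drops trial participants (their
services may be covered by trial budgets and missing from accounting)
and patients from excluded residency regions (care split across
hospitals yields incomplete local data). The filter partitions
exclusions into trial-only / region-only / both so the counts add up,
and it is idempotent.

*Follow-up window.* A case is kept iff its **first** service date lies
in the half-open window `[diagnosis − lookback, diagnosis + fu_days)`.
Defaults: `fu_days = 365`, `lookback = 14` days. The lookback exists
because the diagnostic work-up typically precedes the formal diagnosis
entry; 14 days captures it without pulling in unrelated earlier care.
A case that starts inside the window and runs past its end is kept in
full — costs are summed per case and never prorated at the follow-up
boundary. All cost lines of a kept case are kept (they carry no service
dates of their own).

*Grouping.* One line per case number: first/last billed service date,
the exact decimal sum of the case's cost lines, case type, the union of
admitting and executing units. Money is `Decimal` quantised to
0.01 CHF end to end; the pipeline never accumulates floating point, so
every conservation statement below is exact rather than approximate.
Cost lines whose case number has no service claim (orphans) cannot be
linked to any patient and are excluded with a warning (configurably a
hard failure). Claims of one patient partition across their grouped
cases; the per-patient sum of grouped totals equals the per-patient sum
of retained cost lines exactly.

## Merge step 2 — treatment assignment

Each grouped case is assigned to one or more categories:

* **Systemic therapies** (chemotherapy, immunotherapy, targeted
  therapy): a drug-name token from the modality's dictionary found in
  any claim's service text. A drug match is treated as strong evidence:
  it assigns the case on its own, and by default does not additionally
  require an episode-date overlap.
* **Surgery**: organisational-unit / DRG-text patterns, the case must
  be inpatient, and the case span must overlap a clinical surgery
  episode within a tolerance (default ±7 days — pre-operative work-up
  and discharge examinations billed inside the surgical case sit at the
  episode boundary, and unit patterns alone are weaker evidence than a
  drug name).
* **Radiotherapy**: radiotherapy unit/text patterns plus episode
  overlap, same tolerance.
* **Death in hospital**: set from the clinical death flag on the
  patient's last case (latest last-service date, case-number as
  tie-break), not inferred from cost patterns.
* **Diagnosis**: unmatched cases dated strictly before the first
  treatment start (all of them, not just one — for untreated patients
  everything pre-treatment is diagnostic work-up by construction).
* **Other**: every remaining unmatched case (comorbidity care,
  unassignable follow-up). Complications are assumed to be billed
  within the case of the treatment that triggered them and are not
  separately costed.

Matching is case-insensitive substring matching over claim text and
unit names; the rule engine is entirely dictionary-driven and loadable
from YAML, so the realism of the drug lists and unit patterns is a
configuration concern.

*Cost splitting.* A multi-category case's total is decomposed in three
tiers: (1) drug-attributable cost per matched systemic modality, (2)
radiotherapy-attributable cost lines (cost-centre patterns), (3) the
residual split equally among all assigned categories. Cost lines are
case-level and cannot be traced to individual claims, so tier 1 uses a
configured unit price per drug token multiplied by the matched claim
quantities; with no unit prices configured, tier 1 attributes nothing
(logged) and everything falls into the equal split. Attribution
exceeding the case total is a hard error (corrupt input, not rounding).
Shares are computed in exact decimals; the odd cent from the equal
division goes to the lexicographically first category, a deterministic
tie-break. Shares always sum exactly to the case total, so cost
conservation survives assignment.

*Validation.* The allocation rate per modality is the share of patients
with a clinically recorded episode of that modality for whom at least
one case was assigned to it. On synthetic data the ground-truth ledger
additionally scores per-case category sets and per-(patient, category)
cost totals.

## Outcome analyses

*Utilities.* QLQ-C30 summary scores (0–100, higher better) map to
utilities through a pluggable monotone mapping (affine or
piecewise-linear) loaded from configuration. The repository ships only
a clearly labelled synthetic affine stand-in; published coefficient
sets can be transcribed into the same format. Missing scores stay
missing; baselines are never imputed. The utility change uses the last
available non-missing assessment within the 365-day window, not a
fixed visit; patients without baseline or without any post-baseline
assessment are excluded from correlation analyses.

*Cost summaries.* Costs of a group are first summed per patient, then
summarised across patients: n, median, quartiles (linear interpolation
between order statistics), mean, SD (sample SD, reported as missing for
n = 1), min, max. The category partition {diagnosis, surgery,
radiotherapy, systemic, other, death in hospital} conserves each
patient's grand total exactly.

*Correlations.* Spearman uses average ranks for ties and is flagged not
estimable below 3 complete pairs. The partial correlation of cost and
utility change given covariates (baseline utility + one-hot first
treatment, reference = most frequent modality) residualises both focal
variables on the covariates with an intercept and Pearson-correlates
the residuals; by the Frisch–Waugh–Lovell theorem this equals the
precision-matrix definition, and for this saturated path structure it
is also what an SEM with simultaneous covariate control estimates — so
no latent variables or fit indices are involved. Collinear covariate
columns are dropped (greedy rank check) with a warning; estimation
requires n > k + 2.

## The synthetic generator

The generator emulates what the merge relies on, not lung-cancer
biology:

* one patient ID, several case numbers; inpatient and outpatient claims
  never share a case; an inpatient case number is reused only for a
  readmission within 18 days of discharge (configurable rate, default
  0.10 per surgical case);
* a pre-diagnosis outpatient work-up case (starting 3–10 days before
  the diagnosis date, inside the 14-day lookback), one inpatient case
  per surgery with thoracic-surgery units and DRG-flavoured text,
  outpatient systemic-therapy cases whose claims carry drug names and
  exact list-price drug cost lines, radiotherapy cases under a
  radio-oncology unit, optional comorbidity cases strictly after the
  first treatment start, and a terminal inpatient case for in-hospital
  deaths (the patient's last case by construction);
* cost lines keyed by case number only, billing month lagging the last
  service by a uniform 0–3 months;
* case costs drawn from log-normal distributions parameterised by a
  median and a log-SD (right skew: means exceed medians, as hospital
  cost data do). Defaults (CHF): surgery 40 000, chemotherapy 13 000,
  radiotherapy 17 000, immunotherapy 45 000, targeted therapy 31 500,
  diagnosis 12 000, other 8 000, terminal admission 31 000; σ between
  0.45 and 0.90. Drug costs inside a systemic case are *exact*:
  unit list price × administered quantity, with the quantity chosen to
  hit a per-modality drug-cost fraction of the drawn total and the
  remainder booked as clinic overhead — drug prices are list prices in
  reality, and this is what makes tier-1 attribution exactly testable;
* cohort structure calibrated to a realistic lung-cancer centre: stage
  mix 43/12/16/29% (I–IV), 63% adenocarcinoma, 61% male, median age
  ~71, trial-participation 21.5% and out-of-region 7.85% exclusion
  pressure, stage-dependent death rates with one third of deaths in
  hospital, 18% deactivation among survivors;
* PROM trajectories: truncated-normal baseline (mean 65, SD 15),
  per-visit drift by stage and by newly started treatment, visit noise,
  missing-at-random assessments (8% baseline, 15% follow-up) plus
  monotone dropout after death/deactivation.

Every case is written to a ground-truth ledger with its true category
set and exact decomposition (drug components, radiotherapy component,
residual); ledger shares always sum to the case's cost lines in the
emitted file, also after corruption.

*Inconsistency injection.* Three corruption types seen in real exports:
drug names blanked from service text (unidentifiable systemic therapy),
targeted-therapy drug claims and their cost lines removed (external
pharmacy purchase — the ledger share is reduced accordingly so files
and ledger stay consistent), and orphan cost lines under unknown case
numbers. Each decision consumes one uniform draw per case in a fixed
order, so runs at different rates under the same seed are *nested*: a
case corrupted at rate 0.25 is still corrupted at 0.5. This
common-random-numbers coupling makes sensitivity sweeps (allocation
rate vs blanking rate) monotone by construction instead of only in
expectation.

*What the generator does not emulate* — and hence what passing tests do
not show about real data: clinically realistic treatment policies and
sequencing, survival modelling beyond a stage-dependent hazard,
multi-hospital care paths, claim-level cost heterogeneity beyond the
drug/residual split, same-case co-billing of two systemic therapies
(the engine supports multi-assignment and is tested on constructed
mixed cases, but the default policy bills each course under its own
case number), and the full catalogue of real-world inconsistency types.

## Problem sizes and checks

The test suite validates, among others: exact ledger recovery (100% of
category sets, cent-exact patient–modality totals) on a clean 200-patient
cohort; cost conservation over 1 000 randomly constructed multi-category
cases and through monthly spreading; per-modality median recovery within
10% of the configured medians, pooled over a fixed five-seed family at
500 patients per seed (the pooling keeps the rarest modality, targeted
therapy at ~4% of patients, at a sample size where a 10% band on a
log-normal median is meaningful); estimator-vs-oracle agreement to 1e−10
for the partial correlation and to machine precision for Spearman; and
monotone allocation degradation across blanking rates {0, 0.25, 0.5, 1}
under five seeds. `scripts/acceptance.py` recomputes the same quantities
end to end from a single seed.

## Numerical and degenerate-input conventions

* ISO-8601 dates; one declared format, malformed rows rejected with
  line numbers; duplicate patient IDs and case numbers claimed by two
  patients are hard errors.
* Money: `Decimal`, 2 fractional digits, exact sums; equal splits round
  down with the remainder cent to the first category.
* Monthly spreading: daily rate = case total / (span days, inclusive),
  so a single-day case divides by 1; the case's final month absorbs the
  rounding residue; months beyond follow-up are retained and flagged,
  not dropped (no prorating at the boundary, for censored patients
  either).
* Quantiles: linear interpolation; SD undefined (NaN) at n = 1.
* Empty cohorts/groups: empty reports and omitted summary rows, never
  exceptions.

## Known limitations

* Tier-1 drug attribution relies on configured unit prices; if actual
  billed prices deviate (discounts, dose banding), drug costs are
  mis-split within multi-category cases even though totals remain
  conserved.
* Whether the real merge captured pre-diagnosis work-up via a lookback
  or only via post-diagnosis assignment is unknown; the lookback is a
  flag (`--lookback-days 0` disables it).
* Patients with under 12 months of observation are analysed as
  observed; no imputation or cost extrapolation is attempted, so
  first-year totals are right-censored for them.
* The shipped utility mapping is synthetic; derived utilities are
  placeholders until a published coefficient set is configured.
* No multiple-testing correction across histology × stage strata; the
  correlation tables are exploratory by design.
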
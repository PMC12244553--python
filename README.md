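# vbhc — merging routine hospital datasets for value-based health care

Swiss hospitals routinely collect three datasets that cannot be joined
directly: a **clinical dataset** (clinician- and patient-reported outcomes,
one record per patient), a **service dataset** (billed service claims, keyed
by patient ID *and* case number) and a **cost dataset** produced by the
REKOLE® cost-accounting system (cost lines keyed by case number only — it
carries no patient identifier, and its billing dates lag the services by
months). The *case number* — the billing unit for one inpatient stay or one
up-to-12-month outpatient episode per main diagnosis — is the only key the
service and cost datasets share, and neither dataset states which
overarching treatment (surgery, chemotherapy, radiotherapy, immunotherapy,
targeted therapy) a case belongs to.

`vbhc` implements a two-step merge that turns these three tables into a
per-patient, per-case dataset with treatments and costs attributed, for
lung-cancer care cycles:

1. **Merge step 1 — the grouped dataset.** Filter the cohort to the full
   analysis set (FAS: no trial participants, no out-of-region patients),
   keep case numbers whose first service date falls in the half-open window
   `[diagnosis − lookback, diagnosis + 365 d)`, and reduce to one line per
   case number: first/last billed service date, exact summed cost (decimal
   arithmetic, no float accumulation), case type, organisational units,
   plus the patient's clinical dates (treatment episodes, complications,
   PROM time points).
2. **Merge step 2 — treatment assignment and cost splitting.** A
   dictionary-driven rule engine assigns each case to one or more
   categories using drug-name tokens in the service text (systemic
   therapies), organisational-unit/DRG patterns with episode-date overlap
   (surgery, radiotherapy), the case-type constraint, the clinical
   death-in-hospital flag (last case), and the fallbacks *diagnosis*
   (unmatched, before first treatment) and *other* (comorbidity care).
   When several categories share a case, its cost is split in three tiers:
   (1) drug-attributable costs to the matched systemic therapy, (2)
   radiotherapy-query cost lines to radiotherapy, (3) the remainder equally
   among all assigned categories — shares always sum to the case total to
   the cent.

On top of the merged data the package derives cost summaries by treatment
type / stage / case type (patient-level totals first, then distributional
statistics), per-patient timeline profiles (monthly uniform cost spreading
with QLQ-C30 / utility overlay), and cost–outcome association measures:
Spearman rank correlation and the partial correlation of first-year cost
and utility change from baseline given baseline utility and the type of
first treatment, computed by residualisation (identical to the
precision-matrix definition, and to the saturated-path SEM estimate).

Because the real hospital data are proprietary, the package ships a seeded
**synthetic generator** that emulates the structural constraints of the
three systems (case-number semantics, billing lag, exact-priced drug
lines, right-skewed residual costs, readmission-within-18-days case reuse,
injectable inconsistencies) together with a **ground-truth ledger** that
records every case's true category set and cost decomposition — the oracle
against which the merge is validated.

## Worked example

```sh
vbhc simulate --config examples/generator.yaml --out data/
vbhc validate --clinical data/clinical.csv --service data/service.csv --costs data/costs.csv
vbhc analyze  --clinical data/clinical.csv --service data/service.csv --costs data/costs.csv \
              --out report/ --exclude-region JU
```

With the shipped configuration (200 patients, seed 0) the cost summary by
category (`report/cost_summary_by_category.csv`) reads:

```
            group  n_patients  median    q25    q75   mean     sd    min     max
     chemotherapy          67  11,710  9,134 17,553 14,725  9,846  4,010  52,261
death_in_hospital           5  30,472  9,243 33,465 28,454 21,374  8,518  60,574
        diagnosis         139  12,493  7,954 20,418 15,925 11,619  1,562  71,360
    immunotherapy          36  50,507 32,831 70,650 56,934 37,206 16,750 203,304
            other          73   9,795  4,610 22,104 15,081 14,773    239  63,985
     radiotherapy          36  19,382 13,960 25,934 20,258  9,700  4,987  53,764
          surgery          57  38,738 30,969 65,864 49,272 28,915 18,899 157,204
         systemic          86  25,566 11,681 54,309 38,066 36,462  4,106 228,748
 targeted_therapy           8  25,679 19,039 42,919 29,687 13,188 14,723  47,305
            total         139  63,926 48,295 92,332 73,872 39,133  9,095 271,245
```

All amounts are CHF per patient over the first year after diagnosis
(patient totals per category first, then statistics across patients; the
`systemic` row pools chemo/immuno/targeted; `total` is each FAS patient's
full first-year cost). The medians sit near the generator's configured
log-normal medians (e.g. surgery 40 000, immunotherapy 45 000) — the means
exceed them because the cost models are right-skewed.
`report/correlations.csv` adds, per histology × stage stratum, the Spearman
coefficient and the covariate-adjusted partial correlation between
first-year cost and utility change, e.g.

```
histology      stage   n  spearman  partial
adenocarcinoma I      33    -0.241   -0.158
adenocarcinoma III    11    -0.405   -0.511
```

`vbhc profile --patient P00001 ... --out P00001.svg` renders the
corresponding single-patient timeline (cost area, score/utility lines,
treatment/event bands).

The score-to-utility mapping is pluggable
(`--utility-mapping examples/synthetic_utility_mapping.yaml`); the shipped
file is a labelled synthetic affine stand-in — transcribe a published
coefficient set there to produce real utilities.

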
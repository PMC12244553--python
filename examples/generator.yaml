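# Synthetic-cohort configuration (see docs/methods.md for parameter meaning).
# Omitted keys fall back to the package defaults.
n_patients: 200
seed: 0
fu_days: 365

stage_distribution:
  I: 0.43
  II: 0.12
  III: 0.16
  IV: 0.29

# log-normal case-cost models: median CHF + dispersion (sigma of log);
# drug_fraction is the target share billed as exact-priced drug lines
cost_model:
  surgery: {median: 40000, sigma: 0.55}
  chemotherapy: {median: 13000, sigma: 0.60, drug_fraction: 0.45}
  radiotherapy: {median: 17000, sigma: 0.60}
  immunotherapy: {median: 45000, sigma: 0.55, drug_fraction: 0.72}
  targeted_therapy: {median: 31500, sigma: 0.45, drug_fraction: 0.70}
  diagnosis: {median: 12000, sigma: 0.70}
  other: {median: 8000, sigma: 0.90}
  death_in_hospital: {median: 31000, sigma: 0.60}

# corruption rates applied after generation (all zero = clean datasets)
inconsistency_rates:
  blank_drug: 0.0
  external_pharmacy: 0.0
  orphan_cost: 0.0

# FAS exclusion pressure: trial participation and out-of-region residency
exclusion_rates:
  trial: 0.215
  out_of_region: 0.0785
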
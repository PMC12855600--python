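# Published input table for the aHUS eculizumab-withdrawal cost-utility model.
# One entry per model parameter: mean, standard error and PSA sampling family.
# Omitted SEs default to 10% of the mean (the rule used when no estimate of
# variation was available); family "fixed" means the parameter is never sampled.
# Probabilities/proportions are per 2-week model cycle unless noted.
config:
  starting_age: 20
  male_fraction: 0.51
  cycle_length_days: 14
  discount_rate: 0.035
  horizon_age: 100
  half_cycle_correction: true
parameters:
  # ---- baseline disease distribution (CKD 3 share is the complement) ----
  pct_ckd02: {mean: 0.96, se: 0.096, family: beta, units: proportion}
  # ---- disease progression at relapse, off treatment (probability that a
  #      relapse presents one CKD stage further on) ----
  relapse_progression_ckd02: {mean: 0.25, se: 0.025, family: beta, units: proportion}
  relapse_progression_ckd3: {mean: 0.25, se: 0.025, family: beta, units: proportion}
  # ---- progression to advanced disease (annual probabilities; the
  #      engine converts them to the 2-week cycle) ----
  ckd4_to_esrd: {mean: 0.0255, se: 0.0025, family: beta, units: probability/year}
  esrd_to_transplant: {mean: 0.0325, se: 0.0032, family: beta, units: probability/year}
  transplant_failure: {mean: 0.1164, se: 0.0272, family: lognormal, units: proportion}
  # ---- excess mortality in advanced disease, per cycle ----
  excess_mortality_esrd: {mean: 0.0041, se: 0.0004, family: normal, units: probability/cycle}
  excess_mortality_transplant: {mean: 0.0041, se: 0.0004, family: normal, units: probability/cycle}
  excess_mortality_post_transplant: {mean: 0.0041, se: 0.0004, family: normal, units: probability/cycle}
  # ---- utility values ----
  utility_baseline_ckd03: {mean: 0.86, se: 0.03, family: beta, units: utility}
  utility_transplant_procedure: {mean: 0.66, se: 0.07, family: beta, units: utility}
  # ---- utility increments / decrements ----
  utility_withdrawal_increment: {mean: 0.01, se: 0.02, family: normal, units: utility}
  utility_relapse_decrement: {mean: -0.02, se: 0.04, family: normal, units: utility}
  disutility_ckd4: {mean: -0.15, se: 0.02, family: normal, units: utility}
  disutility_esrd: {mean: -0.21, se: 0.02, family: normal, units: utility}
  disutility_post_transplant: {mean: -0.21, se: 0.02, family: normal, units: utility}
  # ---- drug acquisition costs (per vial; SEs unpublished -> 10% rule) ----
  cost_eculizumab_vial: {mean: 3150, family: gamma, units: GBP/300mg vial}
  cost_ravulizumab_vial: {mean: 16621, family: gamma, units: GBP/1100mg vial}
  pct_home_delivery: {mean: 0.71, se: 0.071, family: beta, units: proportion}
  cost_hospital_delivery: {mean: 1429, se: 142.90, family: gamma, units: GBP/administration}
  cost_antibiotics: {mean: 7, se: 2.59, family: gamma, units: GBP/cycle}
  # ---- disease monitoring costs per cycle ----
  cost_monitoring_maintenance: {mean: 102, se: 10.24, family: gamma, units: GBP/cycle}
  cost_monitoring_withdrawal_month1: {mean: 424, se: 42.37, family: gamma, units: GBP/cycle}
  cost_monitoring_withdrawal_months2_8: {mean: 215, se: 21.53, family: gamma, units: GBP/cycle}
  cost_monitoring_withdrawal_month8plus: {mean: 111, se: 11.11, family: gamma, units: GBP/cycle}
  # ---- disease management costs per cycle ----
  cost_management_withdrawal: {mean: -32, se: 62, family: gamma, units: GBP/cycle}
  cost_management_relapse: {mean: -150, se: 165, family: gamma, units: GBP/cycle}
  cost_management_ckd4: {mean: 18, se: 1.77, family: gamma, units: GBP/cycle}
  cost_management_esrd: {mean: 24, se: 2.36, family: gamma, units: GBP/cycle}
  cost_transplant: {mean: 16037, se: 1564, family: gamma, units: GBP one-off}
  cost_management_post_transplant: {mean: 306, se: 25, family: gamma, units: GBP/cycle}
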
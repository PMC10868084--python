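# Baseline population configuration calibrated to the published baseline
# characteristics of the simulated population (community-dwelling adults 60+).
# Frailty uses the pooled lognormal (natural-scale mean 12.2, SD 9.9 on the
# 0-100 scale) for every subgroup: the per-subgroup table lives in
# supplementary material that is not shipped, so the pooled entry doubles as
# the fallback. social_care prevalence is a synthetic placeholder (not in the
# published baseline table), as is the baseline EQ-5D rule.
schema_version: 1
sample_size: 100000
proportion_female: 0.538
age:
  mean: 70.4
  sd: 7.9
  min: 60
ses_quartile_probabilities: [0.273, 0.184, 0.352, 0.191]
falls_history_probabilities:
  none: 0.746
  single_non_ma: 0.102
  recurrent_non_ma: 0.084
  single_ma: 0.040
  recurrent_ma: 0.028
binary_state_prevalences:
  high_physical_activity: 0.173
  cognitive_impairment: 0.205
  fear_of_falling: 0.068
  abnormal_gait_balance: 0.280
  paid_employment: 0.194
  unpaid_work: 0.274
  oop_care: 0.034
  informal_care: 0.249
  social_care: 0.05
frailty:
  pooled: {mean: 12.2, sd: 9.9}
baseline_eq5d:
  intercept: 0.95
  frailty_slope: -0.009
  age_slope: -0.002
  age_anchor: 70.0
seed: 20240214
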
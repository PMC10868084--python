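# Baseline configuration with sex-specific frailty lognormals: on the 0-1
# index scale men have mean 0.11 (SD 0.09) and women 0.13 (SD 0.10); entries
# below are on the model's 0-100 scale. Other marginals as in the pooled
# baseline configuration.
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
  by_sex:
    male: {mean: 11.0, sd: 9.0}
    female: {mean: 13.0, sd: 10.0}
baseline_eq5d:
  intercept: 0.95
  frailty_slope: -0.009
  age_slope: -0.002
  age_anchor: 70.0
seed: 20240214
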
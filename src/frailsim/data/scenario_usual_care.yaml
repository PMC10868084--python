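# Usual care (UC): current practice. Only falls leading to hospitalisation
# trigger reactive referral; proactive screening is narrower and refers only
# from the Moderate frailty category upward.
#
# Quantities below marked "synthetic" are placeholders for parameters sourced
# from supplementary material that is not shipped (intervention efficacy and
# costs, acute fall costs and utility losses, severity split, mortality rates,
# comorbidity and care-cost tables, LTC sub-model). They are chosen to be
# qualitatively faithful (increasing in severity / frailty / age) and are
# fully config-overridable.
schema_version: 1
strategy: usual_care
label: usual_care
horizon: 40
discount_rate: 0.035
threshold: 20000.0
reactive_eligibility: hospitalised_only
proactive:
  gp_access_equation: gp_access
  screening_probability: 0.10
  referral_min_category: Moderate
self_referral:
  demand_equation: exercise_demand
intervention:          # synthetic
  effect: 0.85
  public_cost: 300.0
  copayment: 50.0
  time_cost: 100.0
# Conditional fall-severity split (synthetic: renormalised one-year history
# shares among fallers), then hospitalisation probability per MA fall.
severity_split:
  single_non_ma: 0.402
  recurrent_non_ma: 0.331
  single_ma: 0.157
  recurrent_ma: 0.110
p_hospitalised_given_ma: 0.3
acute_utility_loss:    # synthetic, per fall by severity
  single_non_ma: 0.002
  recurrent_non_ma: 0.005
  single_ma: 0.020
  recurrent_ma: 0.030
hospitalised_extra_utility_loss: 0.030
acute_cost:            # synthetic, public sector, per fall by severity
  single_non_ma: 0.0
  recurrent_non_ma: 30.0
  single_ma: 350.0
  recurrent_ma: 500.0
hospitalised_extra_cost: 4000.0
# Per-fall fatality probability by sex and age stratum, produced by the
# packaged calibration routine so fatal falls form the published shares of
# all-cause deaths (0.76% men 60-69, 0.45% women 60-69, 1.09% men 70+,
# 0.96% women 70+) under the default mortality table.
fatal_fall_probability:
  male_60_69: 0.00040
  female_60_69: 0.00016
  male_70plus: 0.00190
  female_70plus: 0.00110
mortality:             # synthetic Gompertz-style table, rising in age and frailty
  base_rate: {male: 0.006, female: 0.004}
  age_slope: 0.085
  category_multipliers: {Fit: 1.0, Mild: 1.4, Moderate: 2.2, Severe: 3.5}
  cap: 0.95
ltc:                   # synthetic simplified long-term-care sub-model
  annual_probability: {Fit: 0.000, Mild: 0.002, Moderate: 0.010, Severe: 0.040}
  annual_cost: 35000.0
  public_share_by_ses: [0.3, 0.5, 0.7, 0.9]
  utility: 0.45
  mortality_multiplier: 1.5
costs:                 # synthetic valuation inputs
  comorbidity_by_category: {Fit: 1500.0, Mild: 2500.0, Moderate: 4500.0, Severe: 8000.0}
  private_care_hourly: 18.0
  care_weekly_hours_by_category: {Fit: 1.0, Mild: 2.0, Moderate: 4.0, Severe: 7.0}
  oop_ses_multiplier: [1.2, 1.0, 0.9, 0.8]
  informal_multiple_adl_probability: {Fit: 0.2, Mild: 0.3, Moderate: 0.5, Severe: 0.7}
  informal_multiple_adl_multiplier: 2.0
  paid_employment_annual_value: 25000.0
  unpaid_work_annual_value: 4500.0
halve_eq5d_change: true
annualization_exponent: 0.5
currency_year: GBP 2023
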
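# Logistic regression: incidence of any fall over a two-year window.
# Coefficients (SE) transcribed cell-for-cell from the published table.
# Reference levels: falls_history = none.
schema_version: 1
name: falls_incidence
family: logistic
horizon: two_year
source: published
constant: {coef: 0.067, se: 0.020}
terms:
  - {covariate: age, coef: 0.009, se: 0.004}
  - {covariate: female, coef: 0.187, se: 0.061}
  - {covariate: falls_history, level: single_non_ma, coef: 0.845, se: 0.090}
  - {covariate: falls_history, level: recurrent_non_ma, coef: 1.654, se: 0.102}
  - {covariate: falls_history, level: single_ma, coef: 0.657, se: 0.141}
  - {covariate: falls_history, level: recurrent_ma, coef: 0.974, se: 0.166}
  - {covariate: frailty, coef: 0.049, se: 0.010}
  - {covariate: frailty, transform: square, coef: -0.0007, se: 0.0002}
  - {covariate: fear_of_falling, coef: 0.279, se: 0.125}
  - {covariate: abnormal_gait_balance, coef: 0.148, se: 0.084}
checksum: 5867ea9f469d0e0663f3494482df182d0868d19467880091f9deddce8bd14360
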
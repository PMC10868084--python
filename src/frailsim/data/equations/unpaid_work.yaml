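# Logistic regression: engaging in regular (weekly or more) unpaid work.
# Coefficients (SE) transcribed cell-for-cell from the published table.
# Reference levels: ses_quartile = q1. unpaid_work is the lagged state.
schema_version: 1
name: unpaid_work
family: logistic
horizon: two_year
source: published
constant: {coef: -12.856, se: 2.951}
terms:
  - {covariate: age, coef: 0.331, se: 0.083}
  - {covariate: age, transform: square, coef: -0.002, se: 0.0006}
  - {covariate: female, coef: 0.313, se: 0.065}
  - {covariate: ses_quartile, level: q2, coef: -0.266, se: 0.095}
  - {covariate: ses_quartile, level: q3, coef: -0.233, se: 0.080}
  - {covariate: ses_quartile, level: q4, coef: -0.236, se: 0.098}
  - {covariate: frailty, coef: -0.013, se: 0.005}
  - {covariate: frailty_change, coef: -0.012, se: 0.006}
  - {covariate: cognitive_impairment, coef: -0.379, se: 0.091}
  - {covariate: abnormal_gait_balance, coef: -0.299, se: 0.097}
  - {covariate: unpaid_work, coef: 1.944, se: 0.065}
checksum: b676deb93a4111aba94e95e0821ebbd1191c8b9b29fddebd33654d5b1d9a3cb3
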
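# Linear regression: two-year change in EQ-5D-3L utility index.
# Coefficients (SE) transcribed cell-for-cell from the published table.
# Reference levels: ses_quartile = q1; fall_incidence = none.
# frailty_change is the same-window change in frailty (0-100 scale).
schema_version: 1
name: eq5d_change
family: linear
horizon: two_year
source: published
constant: {coef: 0.500, se: 0.025}
terms:
  - {covariate: age, coef: 0.002, se: 0.0003}
  - {covariate: female, coef: -0.019, se: 0.005}
  - {covariate: ses_quartile, level: q2, coef: -0.019, se: 0.007}
  - {covariate: ses_quartile, level: q3, coef: -0.009, se: 0.006}
  - {covariate: ses_quartile, level: q4, coef: -0.023, se: 0.007}
  - {covariate: fall_incidence, level: single_non_ma, coef: -0.013, se: 0.008}
  - {covariate: fall_incidence, level: recurrent_non_ma, coef: -0.040, se: 0.009}
  - {covariate: fall_incidence, level: single_ma, coef: -0.022, se: 0.012}
  - {covariate: fall_incidence, level: recurrent_ma, coef: -0.0001, se: 0.014}
  - {covariate: frailty, coef: -0.010, se: 0.0004}
  - {covariate: frailty_change, coef: -0.014, se: 0.0004}
  - {covariate: abnormal_gait_balance, coef: -0.017, se: 0.007}
  - {covariate: eq5d, coef: -0.739, se: 0.034}
  - {covariate: eq5d, transform: square, coef: 0.136, se: 0.029}
checksum: 693d1be83a4c99d1f284e3d7744e383f6dbbec4bf3a9366943702ffd72c5455d
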
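# Logistic regression: receipt of out-of-pocket (privately purchased) care.
# Coefficients (SE) transcribed cell-for-cell from the published table.
# Reference levels: ses_quartile = q1. oop_care is the lagged state.
schema_version: 1
name: oop_care
family: logistic
horizon: two_year
source: published
constant: {coef: -10.011, se: 0.763}
terms:
  - {covariate: age, coef: 0.051, se: 0.010}
  - {covariate: female, coef: 0.712, se: 0.172}
  - {covariate: ses_quartile, level: q2, coef: -0.485, se: 0.227}
  - {covariate: ses_quartile, level: q3, coef: -0.698, se: 0.193}
  - {covariate: ses_quartile, level: q4, coef: -1.117, se: 0.247}
  - {covariate: frailty, coef: 0.174, se: 0.027}
  - {covariate: frailty, transform: square, coef: -0.002, se: 0.0005}
  - {covariate: frailty_change, coef: 0.063, se: 0.010}
  - {covariate: high_physical_activity, coef: -0.954, se: 0.435}
  - {covariate: fear_of_falling, coef: 0.659, se: 0.197}
  - {covariate: oop_care, coef: 1.851, se: 0.193}
  - {covariate: informal_care, coef: -0.579, se: 0.181}
checksum: 08196de09d641194e1c96f642ad7666a050876247fde5d2ca5f897f27ee13bc6
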
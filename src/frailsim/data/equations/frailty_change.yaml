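# Linear regression: two-year change in frailty (0-100 scale).
# Coefficients (SE) transcribed cell-for-cell from the published table.
# Reference levels: ses_quartile = q1 (most privileged); fall_incidence = none.
schema_version: 1
name: frailty_change
family: linear
horizon: two_year
source: published
constant: {coef: -5.460, se: 0.696}
terms:
  - {covariate: age, coef: 0.134, se: 0.010}
  - {covariate: ses_quartile, level: q2, coef: 0.089, se: 0.215}
  - {covariate: ses_quartile, level: q3, coef: 0.011, se: 0.184}
  - {covariate: ses_quartile, level: q4, coef: 0.701, se: 0.219}
  - {covariate: fall_incidence, level: single_non_ma, coef: 0.684, se: 0.227}
  - {covariate: fall_incidence, level: recurrent_non_ma, coef: 2.329, se: 0.261}
  - {covariate: fall_incidence, level: single_ma, coef: 1.648, se: 0.350}
  - {covariate: fall_incidence, level: recurrent_ma, coef: 3.870, se: 0.412}
  - {covariate: frailty, coef: -0.198, se: 0.010}
  - {covariate: high_physical_activity, coef: -0.730, se: 0.192}
  - {covariate: cognitive_impairment, coef: 0.620, se: 0.187}
  - {covariate: social_care, coef: 2.643, se: 0.589}
  - {covariate: informal_care, coef: 1.612, se: 0.202}
checksum: a7fa9761ced3a394f4d1df6f22ec2c8975ed69996e47259a1775bb81987e0e67
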
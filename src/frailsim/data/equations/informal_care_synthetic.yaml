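# SYNTHETIC placeholder: logistic regression for receiving informal care.
# Constructed to reproduce the stated qualitative pattern only (receipt
# increases with frailty level and change; strong state persistence).
# informal_care is the lagged state.
schema_version: 1
name: informal_care
family: logistic
horizon: two_year
source: synthetic
constant: {coef: -4.500, se: 0.400}
terms:
  - {covariate: age, coef: 0.030, se: 0.005}
  - {covariate: female, coef: 0.200, se: 0.050}
  - {covariate: frailty, coef: 0.080, se: 0.010}
  - {covariate: frailty_change, coef: 0.050, se: 0.010}
  - {covariate: informal_care, coef: 2.000, se: 0.100}
checksum: dc3c6299ba1b44e75f02fed4d43b9e63d22ede663d22d05d9cb64153d0fdea70
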
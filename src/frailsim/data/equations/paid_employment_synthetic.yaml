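# SYNTHETIC placeholder: logistic regression for being in paid employment.
# Constructed to reproduce the stated qualitative pattern only (negative in
# frailty level and change, declining steeply with age; strong persistence).
# paid_employment is the lagged state.
schema_version: 1
name: paid_employment
family: logistic
horizon: two_year
source: synthetic
constant: {coef: 9.000, se: 1.000}
terms:
  - {covariate: age, coef: -0.135, se: 0.010}
  - {covariate: frailty, coef: -0.030, se: 0.010}
  - {covariate: frailty_change, coef: -0.012, se: 0.006}
  - {covariate: paid_employment, coef: 2.500, se: 0.100}
checksum: 23b59cc3ceb8d8ec6d6d89676a8d50bf2d8cfd114c7334d4d3707e85b2d08076
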
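# SYNTHETIC placeholder: logistic regression for demanding group exercise
# (self-referred pathway). Constructed to reproduce the stated qualitative
# pattern only (demand increases with frailty change) at a modest uptake rate.
schema_version: 1
name: exercise_demand
family: logistic
horizon: two_year
source: synthetic
constant: {coef: -2.500, se: 0.300}
terms:
  - {covariate: frailty, coef: -0.010, se: 0.005}
  - {covariate: frailty_change, coef: 0.050, se: 0.020}
  - {covariate: high_physical_activity, coef: 0.800, se: 0.200}
checksum: 3fdab8464e5b4687658d38b05c99a80e8d1d9c93fd72d05936e90aaf8b4b3045
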
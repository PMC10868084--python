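# SYNTHETIC placeholder: logistic regression for GP contact (proactive
# pathway entry). The original equation lives in supplementary material that
# is not shipped; these coefficients are constructed to reproduce the stated
# qualitative pattern only (access increases with frailty level and with
# frailty change) at plausible contact rates for adults 60+.
schema_version: 1
name: gp_access
family: logistic
horizon: two_year
source: synthetic
constant: {coef: 0.700, se: 0.150}
terms:
  - {covariate: age, coef: 0.010, se: 0.003}
  - {covariate: frailty, coef: 0.020, se: 0.005}
  - {covariate: frailty_change, coef: 0.050, se: 0.010}
checksum: 6593e424ee5cc2feab252aae9bec77478702eb13283713efffff32786fc87535
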
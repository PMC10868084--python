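# Methods

This note documents the model implemented by `frailsim`, its assumptions,
the parameters that matter, what the synthetic inputs do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Model overview

`frailsim` is a discrete individual simulation (DIS): each simulated person
carries a full covariate vector (age, sex, SES quartile, one-year falls
history, 0–100 frailty score, binary activity/care states, EQ-5D-3L utility,
vital and residence status) and advances through annual cycles until death,
long-term-care handling, or the horizon (default 40 years, societal
perspective). Three structural associations organise the cycle:

- **A — the falls–frailty feedback loop.** The fall-incidence logistic
  equation includes frailty and frailty² (risk peaks at a frailty score of
  35 = 0.049/(2·0.0007) and declines beyond, plausibly because the frailest
  are less mobile and less exposed). The frailty-change linear equation
  includes this cycle's fall category, with effects growing with severity
  (+0.684 for a single non-medically-attended fall up to +3.870 for
  recurrent falls with medical attention, per two years). Each feeds the
  other in consecutive cycles.
- **B — secondary effects via frailty.** EQ-5D-3L change, other-cause
  mortality, comorbidity care costs, unpaid work, paid employment, OOP care
  and informal care all depend on the frailty level and/or its change, so a
  fall's consequences propagate beyond the acute event.
- **C — frailty-dependent intervention access.** Reactive referral follows a
  medically-attended fall (any under recommended care, hospitalised-only
  under usual care); proactive access requires a GP contact (probability
  increasing in frailty and frailty change), a positive screen, and frailty
  at or above the scenario's referral category; self-referral follows a
  demand equation increasing in frailty change.

### Cycle order of operations

Pathways → fall event (severity, fatality, acute accrual) → frailty update →
EQ-5D update → other-cause mortality → societal-state redraws and cost
accrual → LTC admission → ageing and falls-history update. The published
diagram numbers the boxes but does not fully pin the within-cycle order;
this order is the package's canonical choice. There is no half-cycle
correction: a person who dies in a cycle accrues that cycle's acute fall
costs but no QALYs, comorbidity or societal flows.

### Falls history

Falls history is a five-category state (none / single non-MA / recurrent
non-MA / single MA / recurrent with MA) with **one-year memory**: this
cycle's fall outcome becomes next cycle's history, and a fall-free year
resets it to "none". This mirrors the one-year recall window of the source
survey wave behind the falls equation. Whether the recurrent categories
should retain longer memory is unknown; one-year memory is the documented
choice.

## Frailty index

52 items (20 chronic diseases, 8 sensory/physical impairments, 1 cognitive
composite, 4 subjective items, 2 lifestyle risks, 15 ADL/IADL limitations,
polypharmacy, living alone; `data/frailty_items.yaml`), scored as deficits
present / items measured. Falls are excluded as an item by validation.
Missing items reduce the denominator, with a configurable completeness floor
(default 80% of items observed) below which profiles are rejected — the
source study instead imputed high-missingness items upstream, which is out
of scope here; denominator reduction is standard deficit-index practice.
Category cutoffs 0.10/0.23/0.37 (each cutoff value belongs to the lower
category, exactly as the published ranges read); `empirical_cutoffs`
recomputes them as the 50th/85th/97th percentiles (linear interpolation) of
any score sample.

## Risk equations

Coefficient tables are shipped as one YAML file per equation, mirroring the
published tables cell for cell, each with an embedded sha256 checksum; the
`validate-coefficients` command reprints every cell for manual proofreading
and fails on drift. Evaluation is strict: a term whose covariate is absent
raises a resolution error naming the equation and covariate — never a
silent zero-fill. Categorical covariates use reference-level coding
(reference carries no term). Linear predictors are clipped to ±700 before
exponentiation and the logistic output is capped one ulp below 1 so
probabilities stay strictly inside (0, 1).

**Covariate coding.** Covariates enter raw (uncentred), exactly as the
printed tables imply. This is flagged prominently: the falls equation's
constant (0.067) combined with raw age yields two-year fall probabilities
near 0.8 for typical profiles, which is implausibly high and suggests the
original model used some unstated centring or coding. Because the original
coding is not stated, the package implements the tables as printed and
exposes per-equation `centering_offsets` in config rather than guessing.
Qualitative results (directions, gradients, pairwise contrasts) are
unaffected; absolute fall counts inherit the uncertainty.

**Horizon conversion.** The source regressions span two-year survey
intervals. Probabilities are annualised as 1 − (1−p)^e with e = 0.5 by
default; the exponent is config-overridable because the falls outcome's
exact window (one-year recall vs two-year interval) is ambiguous. The
halving of two-year frailty change is stated by the source; the EQ-5D change
equation is halved by the same convention (config switch
`halve_eq5d_change`), chosen for symmetric treatment of two-year linear
outcomes.

**Within-cycle sequencing.** This cycle's computed (annualised, clamped)
frailty change is the "change in frailty" covariate of the EQ-5D, unpaid
work, OOP care and informal care equations in the same cycle, mirroring the
wave-to-wave structure of the source regressions (change over the interval
predicting end-of-interval outcomes). Lagged binary states (unpaid work,
OOP care, informal care, paid employment) enter as the previous cycle's
values and are redrawn each cycle.

**PSA.** Only standard errors are printed, so the default perturbation is
independent normal per coefficient; a full variance–covariance matrix is
accepted in config and validated for positive semidefiniteness. Zero-SE
coefficients are left untouched, so point-estimate mode is the degenerate
case.

## Synthetic population

The generator reproduces the published baseline table as *marginals*: age
(normal, SD 7.9, truncated at 60, with the pre-truncation location solved by
root-finding so the post-truncation mean is exactly 70.4), sex, SES quartile
shares, five-category falls-history shares, and binary state prevalences.
The only dependence modelled is the one the source describes: frailty is
drawn conditional on the (age band × sex × SES quartile × falls history)
subgroup from a lognormal moment-matched on the natural 0–100 scale
(σ²_log = ln(1+(sd/mean)²), μ_log = ln(mean) − σ²_log/2), clamped to
[0, 100] (clamping touches <0.05% of draws at the default moments). Binary
states may optionally be made conditional on frailty category via per-
category prevalences; the shipped default uses the pooled marginals.
Correlations between age, sex, SES and the binary states are *not*
emulated — the source table gives no joint distribution — so passing
calibration tests demonstrates marginal, not joint, fidelity.

The per-subgroup frailty table (280 entries) is a supplementary quantity not
available here; the shipped pooled configuration therefore uses the pooled
lognormal (mean 12.2, SD 9.9) for every subgroup, and a second shipped
configuration carries the sex-specific moments (men 11/9, women 13/10 on the
0–100 scale). Any or all of the 280 entries can be supplied in config and
take precedence over the sex-specific and pooled fallbacks.

Baseline EQ-5D-3L is not printed in the source; the default is a
deterministic placeholder, linear in frailty and age
(0.95 − 0.009·frailty − 0.002·(age−70), clamped to the UK tariff range
[−0.594, 1]), anchored so the Fit→Severe utility ordering holds.

**Seeding.** One master seed; individual *i* draws from the substream seeded
by (seed, *i*) with a fixed draw order, so enlarging a cohort never
reshuffles earlier individuals, and identical configs reproduce cohorts
byte-identically. Simulation cycles use substreams keyed by (master seed,
individual, cycle), giving exact common random numbers across scenarios: a
fixed block of 13 uniforms is drawn every cycle regardless of which events
fire, so paired scenario differences isolate the intervention contrast.
The shipped default seed is 20240214.

## Synthetic scenario inputs

The following cycle-level inputs come from supplementary sources that are
not shipped, and are replaced by clearly-labelled synthetic placeholders
(marked in the scenario YAMLs and equation files): fall-severity split
(renormalised one-year history shares among fallers) and hospitalisation
probability; acute fall costs and utility losses by severity; other-cause
mortality (Gompertz-style: base rate per sex × exp(0.085·(band midpoint −
60)) × category multiplier {Fit 1.0, Mild 1.4, Moderate 2.2, Severe 3.5} —
increasing in age and frailty as stated qualitatively); comorbidity costs by
category; the simplified LTC sub-model (annual admission probability by
category, absorbing, with the public cost share varying by SES quartile);
intervention efficacy (single multiplier 0.85 on the annual fall probability
of participants, one-cycle participation) and intervention costs; and the
GP-access, exercise-demand, informal-care and paid-employment equations.
Consequently **absolute cost and QALY levels are illustrative**; what the
model preserves — and what the test suite checks — are the published
coefficient tables, the calibration of the synthetic population, and the
qualitative structure (feedback-loop direction, frailty gradients of utility
and cost, SES gradient of frailty, RC ⊇ UC eligibility).

Per-fall fatality probabilities are derived by the included calibration
routine: for a stratum with mean annual fall probability f and other-cause
mortality m, the per-fall fatality p solving a target fatal-fall share s of
all deaths is p = s·m/(f·(1−s)); the shipped values target shares of 0.76%
(men 60–69), 0.45% (women 60–69), 1.09% (men 70+) and 0.96% (women 70+).

## Outcome accounting

QALY per community cycle = end-of-cycle EQ-5D × 1 year − acute fall utility
decrements. Costs accrue to: public (acute falls, comorbidity by category,
LTC public share, intervention public cost), OOP (private care at
£18/h × weekly hours by category × 52 × an SES multiplier, when the OOP
state is active; intervention co-payments; LTC resident share), informal
care (proxy-goods: the same private-care price, intensity-weighted by the
probability of multiple-ADL dependency), and intervention time costs.
Productivity enters as an offset (human-capital value of paid employment,
opportunity-cost value of unpaid work). Societal cost = public + OOP +
informal + intervention time − productivity, an identity asserted to 1e-9.
Discounting is annual at 3.5% by default (UK convention; the source rate is
not printed), cycle 0 undiscounted. The CEAC is the fraction of PSA draws
with positive incremental net monetary benefit per threshold. The equity
surface is the per-SES-quartile incremental net health benefit
ΔQALY − ΔCost/λ with the q4−q1 gap as the summary (positive = favours the
most deprived); a formal distributional cost-effectiveness analysis is out
of scope.

## Problem sizes and numerical choices

Calibration checks use 100,000-individual cohorts (tolerance: three
Monte-Carlo standard errors, plus a ≤0.02-point allowance on mean frailty
for the deterministic clamp-at-100 bias, which is an order of magnitude
smaller than the Monte-Carlo band). Dynamic property checks use paired
5,000 × 10-cycle runs under common random numbers, where directional
assertions (feedback loop, gradients) are far outside noise. Ties at
category cutoffs resolve downward (cutoff value → lower category).
Degenerate inputs: empty cohorts, zero-SE PSA, identical-score percentile
inputs, single-member subgroups (SE reported as NaN) and empty subgroups
(absent, not zero) are all defined behaviours with tests.

## Known limitations

- Joint baseline covariate structure is not emulated (marginals only, plus
  the frailty-subgroup dependence).
- The raw-coding ambiguity of the falls equation constant (above) inflates
  absolute fall counts; contrasts and gradients are unaffected.
- The LTC sub-model is a simplified absorbing state with fixed utility and
  cost; the richer companion machinery (capacity constraints, falls within
  LTC) is out of scope.
- Intervention efficacy does not vary by frailty, and participation lasts
  one cycle.
- Monetary outputs depend on synthetic valuation inputs and should not be
  read as reproductions of any published aggregate.
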
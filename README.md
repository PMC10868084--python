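# frailsim

A discrete individual simulation (DIS) of community-based falls prevention
for adults aged 60+, in which a 52-item cumulative-deficit frailty index
mediates the falls–frailty feedback loop, long-term health-utility and
mortality trajectories, care costs, societal (non-health) outcomes, and
heterogeneity by demographic and socioeconomic subgroup.

The package is aimed at health-economic modellers who want an
individual-level, annual-cycle framework in which:

- **falls and frailty feed back on one another** — a fall worsens the rate of
  frailty progression, and higher frailty raises the subsequent risk of
  falling;
- **the secondary effects of a fall propagate through frailty** — comorbidity
  health utility, mortality risk, care costs, paid and unpaid productivity,
  out-of-pocket (OOP) care purchase, and informal-care need all respond to
  the frailty level and its change;
- **intervention access depends on frailty and fall history** — reactive,
  proactive (GP contact plus screening), and self-referred prevention
  pathways, with recommended care (RC) and usual care (UC) differing in
  eligibility (e.g. UC refers only *hospitalised* fallers reactively, RC any
  medically-attended faller).

## The model

**Frailty index.** The cumulative-deficit index counts health deficits
present out of 52 measured items and scores the ratio on a 0–1 scale
(multiplied by 100 inside the simulation). Scores are categorised Fit
(0–0.10], Mild (0.10–0.23], Moderate (0.23–0.37] and Severe (>0.37) — the
50th, 85th and 97th percentile cutoffs of the source cohort. Falls are
deliberately *not* an index item, so falls can raise frailty only through
the modelled association.

**Risk equations.** Each outcome is driven by a published multivariate
regression evaluated per individual per cycle. Binary events use the
logistic form

&nbsp;&nbsp;&nbsp;&nbsp;P(event | X) = exp(β₀ + β₁X₁ + … + β_k X_k) / (1 + exp(β₀ + β₁X₁ + … + β_k X_k))

with two-year probabilities annualised by the constant-hazard transform
1 − (1 − p)^½; two-year linear changes (frailty, EQ-5D-3L) are halved.
Coefficient standard errors support probabilistic sensitivity analysis
(PSA). Shipped equations: any-fall incidence; two-year frailty change;
EQ-5D-3L change; regular unpaid work; OOP care receipt; plus clearly-marked
synthetic placeholders for GP access, group-exercise demand, informal-care
receipt and paid employment.

**Population.** A synthetic cohort generator reproduces the baseline
marginals of the simulated population (mean age 70.4, 53.8% female, mean
frailty 12.2, …) and draws each individual's frailty from a lognormal
moment-matched to the (age band × sex × SES quartile × falls history)
subgroup table — 280 subgroups when fully populated, with pooled fallbacks.

**Outcomes.** Per-cycle ledgers accumulate QALYs and costs by payer (public,
OOP, informal care via the proxy-goods approach, productivity via the
human-capital / opportunity-cost approaches, intervention time costs), which
aggregate into discounted totals, ICERs, net monetary benefit,
cost-effectiveness acceptability curves (CEAC), subgroup tables by frailty
category, and per-SES-quartile incremental net health benefit (equity)
summaries.

## Worked example

```python
import dataclasses
from frailsim import (load_baseline_config, generate_cohort, load_default_registry,
                      load_scenario, run_simulation, compare)
from frailsim.outcomes import discounted_totals, equity_summary

config = dataclasses.replace(load_baseline_config("baseline_pooled"), sample_size=2000)
cohort = generate_cohort(config)
registry = load_default_registry()
rc, uc = load_scenario("scenario_recommended_care"), load_scenario("scenario_usual_care")

res_rc = run_simulation(cohort, rc, registry, master_seed=2024, horizon=10)
res_uc = run_simulation(cohort, uc, registry, master_seed=2024, horizon=10)
print(compare(res_rc, res_uc, rate=rc.discount_rate, threshold=rc.threshold))
```

prints (both scenarios replayed under common random numbers, so the paired
differences isolate the eligibility contrast):

```
recommended_care vs usual_care: dQALY=0.0165, dCost=277.78, ICER=16,861, NMB@20,000=51.71
```

i.e. over ten annual cycles recommended care gains 0.0165 discounted QALYs
per person at £277.78 extra societal cost, an ICER of about £16,900 per QALY
— cost-effective at the £20,000 threshold. Grouping the RC run's discounted
totals by frailty category at entry shows the heterogeneity the index is
there to capture — cumulative QALYs fall and public-sector costs rise
monotonically from Fit to Severe:

```
entry category    mean QALY    mean public cost
Fit                   5.96          £21,475
Mild                  4.90          £26,229
Moderate              3.60          £38,110
Severe                1.86          £55,514
```

and `equity_summary(...)` breaks the incremental net health benefit down by
SES quartile (most privileged q1 → most deprived q4) with the q4−q1 gap as
the headline equity statistic. Cost figures for comorbidity care, acute
falls, long-term care and valuation rates are synthetic placeholder inputs
(see `docs/methods.md`), so absolute monetary levels are illustrative;
directions and gradients are the modelled content.

A command-line interface wraps the same library:

```sh
frailsim generate --config baseline.yaml --out cohort.csv --seed 11
frailsim simulate --cohort cohort.csv --scenario rc.yaml --scenario uc.yaml \
    --seed 11 --out-dir results/
frailsim validate-coefficients   # prints every coefficient/SE, verifies checksums
```

Every command writes a `manifest.json` (seed, config hashes, version) from
which the run can be reproduced byte-identically.

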
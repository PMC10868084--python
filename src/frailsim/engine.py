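"""Annual-cycle discrete individual simulation of falls and frailty.

Each community-dwelling individual advances through one-year cycles. Within a
cycle the order of operations is fixed and documented as canonical:

1. prevention-pathway access (reactive on last cycle's medically-attended
   fall, proactive via GP contact plus falls-risk screening, self-referred via
   demand), 2. annual fall probability (falls equation, annualised, times the
   intervention multiplier for participants), 3. on a fall: severity draw,
   fatality check, acute utility/cost accrual, 4. frailty update (annualised
   frailty-change equation given this cycle's fall category, clamped to
   [0, 100]) — the falls-frailty feedback loop, 5. EQ-5D update (utility-change
   equation fed this cycle's frailty change, clamped to tariff bounds),
   6. other-cause mortality by age band, sex and frailty category, 7. societal
   state redraws (unpaid work, paid employment, out-of-pocket care, informal
   care) and cost accrual, 8. long-term-care admission, 9. ageing and
   falls-history update (one-year memory).

A fixed block of uniforms is drawn per individual-cycle from a substream
keyed by (master seed, individual id, cycle), so two scenarios replayed with
the same master seed share every event draw (common random numbers) and
paired differences isolate the intervention effect.

The recommended-care / usual-care contrast enters through pathway
eligibility: usual care refers only *hospitalised* fallers to the reactive
pathway, recommended care refers any medically-attended faller, and screens
more broadly on the proactive pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import (
    DEFAULT_AGE_BAND_EDGES,
    EQ5D_CEILING,
    EQ5D_FLOOR,
    FALL_CATEGORIES,
    FRAILTY_CATEGORIES,
)
from .equations import EquationRegistry
from .errors import ConfigurationError, InvariantViolation
from .frailty import categorize, category_index, rescale_from_model_scale
from .population import IndividualState, age_group_of

__all__ = [
    "ScenarioConfig",
    "CycleEvent",
    "SimulationResult",
    "run_cycle",
    "run_simulation",
    "pathway_eligibility",
    "update_falls_history",
    "calibrate_fatal_fall_probabilities",
    "load_scenario",
]

MA_CATEGORIES = ("single_ma", "recurrent_ma")
FALL_SEVERITIES = FALL_CATEGORIES[1:]  # everything except "none"

# Named indices into the per-cycle uniform block (drawn unconditionally so
# common random numbers stay aligned across scenarios).
N_DRAWS = 13
(U_GP, U_SCREEN, U_DEMAND, U_FALL, U_SEVERITY, U_HOSP, U_FATAL, U_MORT,
 U_UNPAID, U_PAID, U_OOP, U_INFORMAL, U_LTC) = range(N_DRAWS)

LEDGER_COLUMNS = (
    "qaly",
    "public_cost",
    "oop_cost",
    "informal_care_cost",
    "productivity_value",
    "intervention_time_cost",
)


@dataclass(frozen=True)
class CycleEvent:
    """What happened to one individual in one cycle."""

    individual_id: int
    cycle: int
    fall_outcome: str = "none"
    hospitalised: bool = False
    fatal_fall: bool = False
    died_other_cause: bool = False
    interventions_received: frozenset = frozenset()
    frailty_change_applied: float = 0.0
    eq5d_change_applied: float = 0.0

    def __post_init__(self) -> None:
        if self.fatal_fall and self.fall_outcome == "none":
            raise InvariantViolation("fatal fall recorded without a fall outcome")
        if self.fatal_fall and self.died_other_cause:
            raise InvariantViolation("at most one death cause per cycle")


@dataclass
class MortalityModel:
    """Annual other-cause mortality by age band, sex and frailty category.

    Synthetic default (the published rate curves are not reproduced here):
    a Gompertz-style base rate per sex rising with the age-band midpoint,
    scaled by a frailty-category multiplier — increasing in both age and
    frailty, matching the stated qualitative gradient.
    """

    base_rate: dict[str, float]
    age_slope: float
    category_multipliers: dict[str, float]
    cap: float = 0.95
    band_midpoints: tuple[float, ...] = (62.5, 67.5, 72.5, 77.5, 82.5, 87.5, 92.5)
    explicit: dict[tuple[int, str, str], float] = field(default_factory=dict)

    def rate(self, age_band: int, sex: str, category: str) -> float:
        key = (age_band, sex, category)
        if key in self.explicit:
            return self.explicit[key]
        mid = self.band_midpoints[age_band - 1]
        r = (
            self.base_rate[sex]
            * np.exp(self.age_slope * (mid - 60.0))
            * self.category_multipliers[category]
        )
        return float(min(r, self.cap))


@dataclass
class ScenarioConfig:
    """One intervention strategy plus all cycle-level parameter tables."""

    strategy: str
    horizon: int
    discount_rate: float
    threshold: float
    reactive_eligibility: str  # "any_ma" (recommended care) | "hospitalised_only"
    screening_probability: float
    referral_min_category: str  # lowest frailty category referred after screening
    gp_access_equation: str = "gp_access"
    demand_equation: str = "exercise_demand"
    intervention_effect: float = 0.85  # multiplier on annual fall probability
    intervention_public_cost: float = 300.0
    intervention_copayment: float = 50.0
    intervention_time_cost: float = 100.0
    severity_split: dict[str, float] = field(default_factory=dict)
    p_hospitalised_given_ma: float = 0.3
    acute_utility_loss: dict[str, float] = field(default_factory=dict)
    acute_cost: dict[str, float] = field(default_factory=dict)
    hospitalised_extra_utility_loss: float = 0.03
    hospitalised_extra_cost: float = 4000.0
    fatal_fall_probability: dict[str, float] = field(default_factory=dict)
    mortality: MortalityModel = None  # type: ignore[assignment]
    ltc_annual_probability: dict[str, float] = field(default_factory=dict)
    ltc_annual_cost: float = 35000.0
    ltc_public_share_by_ses: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)
    ltc_utility: float = 0.45
    ltc_mortality_multiplier: float = 1.5
    comorbidity_cost_by_category: dict[str, float] = field(default_factory=dict)
    private_care_hourly: float = 18.0
    care_weekly_hours_by_category: dict[str, float] = field(default_factory=dict)
    oop_ses_multiplier: tuple[float, ...] = (1.2, 1.0, 0.9, 0.8)
    informal_multiple_adl_probability: dict[str, float] = field(default_factory=dict)
    informal_multiple_adl_multiplier: float = 2.0
    paid_employment_annual_value: float = 25000.0
    unpaid_work_annual_value: float = 4500.0
    halve_eq5d_change: bool = True
    annualization_exponent: float = 0.5
    fall_probability_override: float | None = None
    currency_year: str = "GBP 2023"
    label: str = ""

    def __post_init__(self) -> None:
        if self.strategy not in ("recommended_care", "usual_care"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.reactive_eligibility not in ("any_ma", "hospitalised_only"):
            raise ConfigurationError(
                f"unknown reactive eligibility {self.reactive_eligibility!r}"
            )
        if not 0.0 < self.intervention_effect <= 1.0:
            raise ConfigurationError("intervention_effect must lie in (0, 1]")
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")
        if self.discount_rate < 0:
            raise ConfigurationError("discount rate must be non-negative")
        split = [self.severity_split.get(s, 0.0) for s in FALL_SEVERITIES]
        if abs(sum(split) - 1.0) > 1e-9:
            raise ConfigurationError(f"severity_split sums to {sum(split)}, not 1")
        self._severity_cumulative = np.cumsum(split)[:-1]
        if self.referral_min_category not in FRAILTY_CATEGORIES:
            raise ConfigurationError(
                f"unknown referral category {self.referral_min_category!r}"
            )
        if not self.label:
            self.label = self.strategy

    def fatal_p(self, sex: str, age: float) -> float:
        stratum = f"{sex}_60_69" if age < 70 else f"{sex}_70plus"
        return self.fatal_fall_probability.get(stratum, 0.0)


def update_falls_history(previous_history: str, fall_outcome: str) -> str:
    """One-year falls-history memory: this cycle's outcome becomes next
    cycle's history; no fall means no falls history."""
    if previous_history not in FALL_CATEGORIES:
        raise ValueError(f"unknown history category {previous_history!r}")
    if fall_outcome not in FALL_CATEGORIES:
        raise ValueError(f"unknown fall outcome {fall_outcome!r}")
    return fall_outcome


def pathway_eligibility(
    individual: IndividualState,
    prior_event: CycleEvent | None,
    scenario: ScenarioConfig,
    *,
    gp_contact: bool = False,
    screened_positive: bool = False,
    self_demand: bool = False,
) -> frozenset:
    """Which prevention pathways the individual enters this cycle.

    Reactive eligibility is deterministic in the prior cycle's fall: under
    recommended care any medically-attended fall qualifies, under usual care
    only a hospitalised one. Proactive requires a GP contact, a positive
    screen, and frailty at or above the referral category. Recommended-care
    reactive eligibility is a superset of usual care's for every input.
    """
    pathways = set()
    if prior_event is not None and prior_event.fall_outcome in MA_CATEGORIES:
        if scenario.reactive_eligibility == "any_ma" or prior_event.hospitalised:
            pathways.add("reactive")
    if gp_contact and screened_positive:
        if category_index(individual.frailty_category) >= category_index(
            scenario.referral_min_category
        ):
            pathways.add("proactive")
    if self_demand:
        pathways.add("self_referred")
    return frozenset(pathways)


def _covariates(ind: IndividualState) -> dict:
    return {
        "age": ind.age,
        "female": 1.0 if ind.sex == "female" else 0.0,
        "ses_quartile": f"q{ind.ses_quartile}",
        "falls_history": ind.falls_history,
        "fall_incidence": "none",
        "frailty": ind.frailty,
        "frailty_change": 0.0,
        "eq5d": ind.eq5d,
        "fear_of_falling": 1.0 if ind.fear_of_falling else 0.0,
        "abnormal_gait_balance": 1.0 if ind.abnormal_gait_balance else 0.0,
        "high_physical_activity": 1.0 if ind.high_physical_activity else 0.0,
        "cognitive_impairment": 1.0 if ind.cognitive_impairment else 0.0,
        "social_care": 1.0 if ind.social_care else 0.0,
        "informal_care": 1.0 if ind.informal_care else 0.0,
        "unpaid_work": 1.0 if ind.unpaid_work else 0.0,
        "oop_care": 1.0 if ind.oop_care else 0.0,
        "paid_employment": 1.0 if ind.paid_employment else 0.0,
    }


def _check_probability(p: float, what: str) -> float:
    if not 0.0 <= p <= 1.0:
        raise InvariantViolation(f"{what} composed to {p}, outside [0, 1]")
    return p


def run_cycle(
    individual: IndividualState,
    scenario: ScenarioConfig,
    registry: EquationRegistry,
    rng: np.random.Generator,
    prior_event: CycleEvent | None = None,
    cycle: int = 0,
) -> tuple[IndividualState, CycleEvent, dict]:
    """Advance one alive, community-dwelling individual by one year.

    Mutates ``individual`` in place and returns it together with the cycle's
    event record and ledger row. A cycle in which the individual dies accrues
    acute fall costs only — no QALYs, comorbidity or societal flows (annual
    accrual without half-cycle correction).
    """
    if not individual.alive:
        raise ValueError(f"individual {individual.id} is dead; run_cycle requires alive")
    if individual.residence != "community":
        raise ValueError(
            f"individual {individual.id} is in {individual.residence}; "
            "run_cycle requires community residence"
        )
    u = rng.random(N_DRAWS)
    cov = _covariates(individual)
    exponent = scenario.annualization_exponent

    # 1. pathway access
    p_gp = _check_probability(
        registry.evaluate(scenario.gp_access_equation, cov,
                          annualization_exponent=exponent), "GP access probability")
    p_demand = _check_probability(
        registry.evaluate(scenario.demand_equation, cov,
                          annualization_exponent=exponent), "demand probability")
    pathways = pathway_eligibility(
        individual,
        prior_event,
        scenario,
        gp_contact=u[U_GP] < p_gp,
        screened_positive=u[U_SCREEN] < scenario.screening_probability,
        self_demand=u[U_DEMAND] < p_demand,
    )
    participating = bool(pathways)

    # 2. annual fall probability
    if scenario.fall_probability_override is not None:
        p_fall = scenario.fall_probability_override
    else:
        p_fall = registry.evaluate("falls_incidence", cov,
                                   annualization_exponent=exponent)
    if participating:
        p_fall *= scenario.intervention_effect
    p_fall = _check_probability(p_fall, "annual fall probability")

    # 3. fall event, severity, fatality, acute accrual
    fall_outcome = "none"
    hospitalised = False
    fatal_fall = False
    acute_utility_loss = 0.0
    acute_cost = 0.0
    if u[U_FALL] < p_fall:
        sev_idx = int(np.searchsorted(scenario._severity_cumulative, u[U_SEVERITY],
                                      side="right"))
        fall_outcome = FALL_SEVERITIES[min(sev_idx, len(FALL_SEVERITIES) - 1)]
        if fall_outcome in MA_CATEGORIES:
            # For recurrent fallers with medical attention this is the
            # configured probability that the (second) MA fall is hospitalised.
            hospitalised = u[U_HOSP] < scenario.p_hospitalised_given_ma
        acute_utility_loss = scenario.acute_utility_loss.get(fall_outcome, 0.0)
        acute_cost = scenario.acute_cost.get(fall_outcome, 0.0)
        if hospitalised:
            acute_utility_loss += scenario.hospitalised_extra_utility_loss
            acute_cost += scenario.hospitalised_extra_cost
        fatal_fall = u[U_FATAL] < scenario.fatal_p(individual.sex, individual.age)

    # 4. frailty update (feedback loop): this cycle's fall category feeds the
    # frailty-change equation; the two-year prediction is halved.
    cov["fall_incidence"] = fall_outcome
    old_frailty = individual.frailty
    annual_frailty_change = registry.evaluate("frailty_change", cov)
    new_frailty = float(np.clip(old_frailty + annual_frailty_change, 0.0, 100.0))
    frailty_change_applied = new_frailty - old_frailty

    # 5. EQ-5D update: frailty level enters at its start-of-cycle value, the
    # frailty change is this cycle's applied (annualised) change.
    cov["frailty_change"] = frailty_change_applied
    eq5d_change = registry.evaluate("eq5d_change", cov,
                                    annualize=scenario.halve_eq5d_change)
    new_eq5d = float(np.clip(individual.eq5d + eq5d_change, EQ5D_FLOOR, EQ5D_CEILING))
    eq5d_change_applied = new_eq5d - individual.eq5d
    individual.frailty = new_frailty
    individual.eq5d = new_eq5d
    category = individual.frailty_category

    # 6. mortality
    died_other = False
    if fatal_fall:
        individual.alive = False
    else:
        m = scenario.mortality.rate(age_group_of(individual.age), individual.sex,
                                    category)
        died_other = u[U_MORT] < _check_probability(m, "other-cause mortality rate")
        if died_other:
            individual.alive = False

    ledger = dict.fromkeys(LEDGER_COLUMNS, 0.0)
    ledger["public_cost"] = acute_cost

    if individual.alive:
        # 7. societal-state redraws (lagged states feed the equations) and accrual
        cov["frailty"] = old_frailty  # equations are anchored at start-of-window level
        p_unpaid = registry.evaluate("unpaid_work", cov,
                                     annualization_exponent=exponent)
        p_paid = registry.evaluate("paid_employment", cov,
                                   annualization_exponent=exponent)
        p_oop = registry.evaluate("oop_care", cov, annualization_exponent=exponent)
        p_informal = registry.evaluate("informal_care", cov,
                                       annualization_exponent=exponent)
        individual.unpaid_work = bool(u[U_UNPAID] < p_unpaid)
        individual.paid_employment = bool(u[U_PAID] < p_paid)
        individual.oop_care = bool(u[U_OOP] < p_oop)
        individual.informal_care = bool(u[U_INFORMAL] < p_informal)

        ledger["qaly"] = new_eq5d - acute_utility_loss
        ledger["public_cost"] += scenario.comorbidity_cost_by_category[category]
        weekly_hours = scenario.care_weekly_hours_by_category[category]
        annual_care_cost = scenario.private_care_hourly * weekly_hours * 52.0
        if individual.oop_care:
            ledger["oop_cost"] += (
                annual_care_cost * scenario.oop_ses_multiplier[individual.ses_quartile - 1]
            )
        if individual.informal_care:
            # proxy-goods valuation: informal care priced as the OOP substitute,
            # intensity-weighted by the chance of multiple-ADL dependency
            p_multi = scenario.informal_multiple_adl_probability[category]
            intensity = 1.0 + (scenario.informal_multiple_adl_multiplier - 1.0) * p_multi
            ledger["informal_care_cost"] += annual_care_cost * intensity
        if individual.paid_employment:
            ledger["productivity_value"] += scenario.paid_employment_annual_value
        if individual.unpaid_work:
            ledger["productivity_value"] += scenario.unpaid_work_annual_value
        if participating:
            ledger["public_cost"] += scenario.intervention_public_cost
            ledger["oop_cost"] += scenario.intervention_copayment
            ledger["intervention_time_cost"] += scenario.intervention_time_cost

        # 8. long-term-care admission (absorbing community exit)
        if u[U_LTC] < scenario.ltc_annual_probability[category]:
            individual.residence = "long_term_care"

    # 9. ageing and one-year falls-history memory
    individual.age += 1.0
    individual.falls_history = update_falls_history(individual.falls_history,
                                                    fall_outcome)
    event = CycleEvent(
        individual_id=individual.id,
        cycle=cycle,
        fall_outcome=fall_outcome,
        hospitalised=hospitalised,
        fatal_fall=fatal_fall,
        died_other_cause=died_other,
        interventions_received=pathways,
        frailty_change_applied=frailty_change_applied,
        eq5d_change_applied=eq5d_change_applied,
    )
    return individual, event, ledger


def _ltc_cycle(
    individual: IndividualState, scenario: ScenarioConfig, rng: np.random.Generator
) -> dict:
    """Simplified long-term-care year: fixed utility, LTC costs split between
    the public purse and residents by SES quartile, elevated mortality."""
    u = rng.random(N_DRAWS)
    m = scenario.mortality.rate(age_group_of(individual.age), individual.sex,
                                "Severe") * scenario.ltc_mortality_multiplier
    ledger = dict.fromkeys(LEDGER_COLUMNS, 0.0)
    if u[U_MORT] < min(m, 1.0):
        individual.alive = False
    else:
        share = scenario.ltc_public_share_by_ses[individual.ses_quartile - 1]
        ledger["qaly"] = scenario.ltc_utility
        ledger["public_cost"] = scenario.ltc_annual_cost * share
        ledger["oop_cost"] = scenario.ltc_annual_cost * (1.0 - share)
        individual.eq5d = scenario.ltc_utility
    individual.age += 1.0
    return ledger


@dataclass
class SimulationResult:
    """Per-individual-per-cycle trajectory and ledger rows plus final states."""

    cycles: pd.DataFrame
    final_states: list[IndividualState]
    scenario_label: str
    master_seed: int
    horizon: int

    def alive_counts(self) -> pd.Series:
        return self.cycles.groupby("cycle")["alive"].sum()


def run_simulation(
    cohort: list[IndividualState],
    scenario: ScenarioConfig,
    registry: EquationRegistry,
    master_seed: int,
    horizon: int | None = None,
) -> SimulationResult:
    """Run every individual to death, long-term care with continued accrual,
    or the horizon. The input cohort is not mutated, so the same cohort can be
    replayed under a second scenario with the same master seed for a paired
    (common-random-numbers) comparison."""
    horizon = scenario.horizon if horizon is None else horizon
    if horizon < 1:
        raise ConfigurationError("horizon must be >= 1")
    rows: list[dict] = []
    finals: list[IndividualState] = []
    for source in cohort:
        ind = source.copy()
        prior: CycleEvent | None = None
        for cycle in range(horizon):
            if not ind.alive:
                break
            rng = np.random.default_rng([master_seed, ind.id, cycle])
            if ind.residence == "community":
                ind, event, ledger = run_cycle(ind, scenario, registry, rng,
                                               prior_event=prior, cycle=cycle)
                prior = event
            else:
                ledger = _ltc_cycle(ind, scenario, rng)
                event = CycleEvent(individual_id=ind.id, cycle=cycle)
            row = {
                "id": ind.id,
                "cycle": cycle,
                "scenario": scenario.label,
                "alive": ind.alive,
                "residence": ind.residence,
                "age": ind.age,
                "sex": ind.sex,
                "ses_quartile": ind.ses_quartile,
                "frailty": ind.frailty,
                "frailty_category": ind.frailty_category,
                "eq5d": ind.eq5d,
                "fall_outcome": event.fall_outcome,
                "fatal_fall": event.fatal_fall,
                "died_other_cause": event.died_other_cause,
                "participated": bool(event.interventions_received),
                **ledger,
            }
            rows.append(row)
        finals.append(ind)
    cycles = pd.DataFrame(rows)
    return SimulationResult(
        cycles=cycles,
        final_states=finals,
        scenario_label=scenario.label,
        master_seed=master_seed,
        horizon=horizon,
    )


def calibrate_fatal_fall_probabilities(
    cohort: list[IndividualState],
    scenario: ScenarioConfig,
    registry: EquationRegistry,
    target_shares: dict[str, float],
) -> dict[str, float]:
    """Invert per-fall fatality probabilities from target fatal-fall shares of
    all-cause mortality.

    For a stratum with mean annual fall probability f and mean other-cause
    mortality m, a per-fall fatality p gives a fatal-fall share of deaths
    s = f*p / (f*p + m), hence p = s*m / (f*(1-s)).
    """
    groups: dict[str, list[IndividualState]] = {k: [] for k in target_shares}
    for ind in cohort:
        stratum = f"{ind.sex}_60_69" if ind.age < 70 else f"{ind.sex}_70plus"
        if stratum in groups:
            groups[stratum].append(ind)
    out = {}
    for stratum, members in groups.items():
        if not members:
            raise ConfigurationError(f"no cohort members in stratum {stratum}")
        s = target_shares[stratum]
        f = float(np.mean([
            registry.evaluate("falls_incidence", _covariates(ind),
                              annualization_exponent=scenario.annualization_exponent)
            for ind in members
        ]))
        m = float(np.mean([
            scenario.mortality.rate(age_group_of(ind.age), ind.sex,
                                    ind.frailty_category)
            for ind in members
        ]))
        out[stratum] = s * m / (f * (1.0 - s))
    return out


# ---------------------------------------------------------------------------
# Scenario loading


def load_scenario(source) -> ScenarioConfig:
    """Load a scenario YAML from a path, shipped stem name, or literal text."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(str(source)).read_text()
    elif isinstance(source, str) and "\n" not in source:
        text = resources.files("frailsim.data").joinpath(f"{source}.yaml").read_text()
    else:
        text = str(source)
    raw = yaml.safe_load(text)
    mort = raw["mortality"]
    model = MortalityModel(
        base_rate={k: float(v) for k, v in mort["base_rate"].items()},
        age_slope=float(mort["age_slope"]),
        category_multipliers={k: float(v) for k, v in mort["category_multipliers"].items()},
        cap=float(mort.get("cap", 0.95)),
        explicit={
            (int(e["age_band"]), e["sex"], e["category"]): float(e["rate"])
            for e in mort.get("explicit", [])
        },
    )
    interv = raw.get("intervention", {})
    ltc = raw.get("ltc", {})
    costs = raw.get("costs", {})
    return ScenarioConfig(
        strategy=raw["strategy"],
        horizon=int(raw["horizon"]),
        discount_rate=float(raw["discount_rate"]),
        threshold=float(raw["threshold"]),
        reactive_eligibility=raw["reactive_eligibility"],
        screening_probability=float(raw["proactive"]["screening_probability"]),
        referral_min_category=raw["proactive"]["referral_min_category"],
        gp_access_equation=raw["proactive"].get("gp_access_equation", "gp_access"),
        demand_equation=raw.get("self_referral", {}).get("demand_equation",
                                                         "exercise_demand"),
        intervention_effect=float(interv.get("effect", 0.85)),
        intervention_public_cost=float(interv.get("public_cost", 300.0)),
        intervention_copayment=float(interv.get("copayment", 50.0)),
        intervention_time_cost=float(interv.get("time_cost", 100.0)),
        severity_split={k: float(v) for k, v in raw["severity_split"].items()},
        p_hospitalised_given_ma=float(raw.get("p_hospitalised_given_ma", 0.3)),
        acute_utility_loss={k: float(v) for k, v in raw["acute_utility_loss"].items()},
        acute_cost={k: float(v) for k, v in raw["acute_cost"].items()},
        hospitalised_extra_utility_loss=float(
            raw.get("hospitalised_extra_utility_loss", 0.03)),
        hospitalised_extra_cost=float(raw.get("hospitalised_extra_cost", 4000.0)),
        fatal_fall_probability={k: float(v)
                                for k, v in raw["fatal_fall_probability"].items()},
        mortality=model,
        ltc_annual_probability={k: float(v)
                                for k, v in ltc["annual_probability"].items()},
        ltc_annual_cost=float(ltc.get("annual_cost", 35000.0)),
        ltc_public_share_by_ses=tuple(float(x) for x in
                                      ltc.get("public_share_by_ses",
                                              (0.3, 0.5, 0.7, 0.9))),
        ltc_utility=float(ltc.get("utility", 0.45)),
        ltc_mortality_multiplier=float(ltc.get("mortality_multiplier", 1.5)),
        comorbidity_cost_by_category={k: float(v) for k, v in
                                      costs["comorbidity_by_category"].items()},
        private_care_hourly=float(costs.get("private_care_hourly", 18.0)),
        care_weekly_hours_by_category={k: float(v) for k, v in
                                       costs["care_weekly_hours_by_category"].items()},
        oop_ses_multiplier=tuple(float(x) for x in
                                 costs.get("oop_ses_multiplier", (1.2, 1.0, 0.9, 0.8))),
        informal_multiple_adl_probability={
            k: float(v) for k, v in
            costs["informal_multiple_adl_probability"].items()},
        informal_multiple_adl_multiplier=float(
            costs.get("informal_multiple_adl_multiplier", 2.0)),
        paid_employment_annual_value=float(
            costs.get("paid_employment_annual_value", 25000.0)),
        unpaid_work_annual_value=float(costs.get("unpaid_work_annual_value", 4500.0)),
        halve_eq5d_change=bool(raw.get("halve_eq5d_change", True)),
        annualization_exponent=float(raw.get("annualization_exponent", 0.5)),
        currency_year=str(raw.get("currency_year", "GBP 2023")),
        label=str(raw.get("label", "")),
    )
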
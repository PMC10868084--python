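"""Simulation engine: cycle mechanics, pathways, feedback loop, state sanity."""

import dataclasses

import numpy as np
import pytest

from frailsim.constants import EQ5D_FLOOR, FALL_CATEGORIES
from frailsim.engine import (
    N_DRAWS,
    U_FALL,
    U_SEVERITY,
    CycleEvent,
    calibrate_fatal_fall_probabilities,
    pathway_eligibility,
    run_cycle,
    run_simulation,
    update_falls_history,
)
from frailsim.errors import InvariantViolation
from frailsim.population import IndividualState


def make_individual(**overrides):
    kwargs = dict(
        id=0, age=70.0, sex="male", ses_quartile=1, falls_history="none",
        frailty=20.0, eq5d=0.8,
    )
    kwargs.update(overrides)
    return IndividualState(**kwargs)


class ScriptedRNG:
    """Stands in for a Generator: returns a fixed uniform block."""

    def __init__(self, uniforms):
        self.uniforms = np.asarray(uniforms, dtype=float)

    def random(self, n=None):
        assert n == len(self.uniforms)
        return self.uniforms


class TestFallsHistoryUpdate:
    def test_no_fall_resets_history(self):
        for prev in FALL_CATEGORIES:
            assert update_falls_history(prev, "none") == "none"

    def test_outcome_carries_to_next_cycle(self):
        assert update_falls_history("none", "single_ma") == "single_ma"

    def test_total_over_all_25_input_pairs(self):
        for prev in FALL_CATEGORIES:
            for outcome in FALL_CATEGORIES:
                assert update_falls_history(prev, outcome) == outcome

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            update_falls_history("none", "tumble")


class TestPathwayEligibility:
    @pytest.mark.parametrize("outcome", FALL_CATEGORIES)
    @pytest.mark.parametrize("hospitalised", [False, True])
    def test_recommended_care_reactive_contains_usual_care(
        self, rc_scenario, uc_scenario, outcome, hospitalised
    ):
        ind = make_individual()
        prior = CycleEvent(individual_id=0, cycle=0, fall_outcome=outcome,
                           hospitalised=hospitalised)
        rc = pathway_eligibility(ind, prior, rc_scenario)
        uc = pathway_eligibility(ind, prior, uc_scenario)
        assert uc <= rc

    def test_ma_non_hospitalised_fall_reactive_under_rc_only(
        self, rc_scenario, uc_scenario
    ):
        ind = make_individual()
        prior = CycleEvent(individual_id=0, cycle=0, fall_outcome="single_ma",
                           hospitalised=False)
        assert "reactive" in pathway_eligibility(ind, prior, rc_scenario)
        assert "reactive" not in pathway_eligibility(ind, prior, uc_scenario)

    def test_hospitalised_fall_reactive_under_both(self, rc_scenario, uc_scenario):
        ind = make_individual()
        prior = CycleEvent(individual_id=0, cycle=0, fall_outcome="recurrent_ma",
                           hospitalised=True)
        assert "reactive" in pathway_eligibility(ind, prior, rc_scenario)
        assert "reactive" in pathway_eligibility(ind, prior, uc_scenario)

    def test_nothing_triggers_empty_set(self, rc_scenario):
        assert pathway_eligibility(make_individual(), None, rc_scenario) == frozenset()

    def test_proactive_needs_frailty_at_referral_category(self, rc_scenario):
        fit = make_individual(frailty=5.0)       # Fit, below RC's Mild referral floor
        mild = make_individual(frailty=15.0)     # Mild
        kwargs = dict(gp_contact=True, screened_positive=True)
        assert "proactive" not in pathway_eligibility(fit, None, rc_scenario, **kwargs)
        assert "proactive" in pathway_eligibility(mild, None, rc_scenario, **kwargs)


class TestRunCycle:
    def test_dead_individual_rejected(self, rc_scenario, registry):
        ind = make_individual(alive=False)
        with pytest.raises(ValueError, match="dead"):
            run_cycle(ind, rc_scenario, registry, np.random.default_rng(0))

    def test_ltc_resident_rejected(self, rc_scenario, registry):
        ind = make_individual(residence="long_term_care")
        with pytest.raises(ValueError, match="long_term_care"):
            run_cycle(ind, rc_scenario, registry, np.random.default_rng(0))

    def test_scripted_fall_reproduces_hand_computed_updates(self, rc_scenario, registry):
        """A forced recurrent non-MA fall for a 70-year-old man (most
        privileged quartile, frailty 20, no flags, EQ-5D 0.8): frailty and
        EQ-5D updates equal spreadsheet-style predictions from the published
        coefficient tables, annualised."""
        ind = make_individual()
        u = np.full(N_DRAWS, 0.999)  # suppress every other stochastic event
        u[U_FALL] = 0.0              # force a fall
        u[U_SEVERITY] = 0.5          # cumulative split -> recurrent non-MA
        _, event, ledger = run_cycle(ind, rc_scenario, registry, ScriptedRNG(u))
        assert event.fall_outcome == "recurrent_non_ma"

        # two-year frailty change, halved
        d_frailty_2y = -5.460 + 0.134 * 70.0 + 2.329 - 0.198 * 20.0
        expected_frailty = 20.0 + d_frailty_2y / 2.0
        assert ind.frailty == pytest.approx(expected_frailty, abs=1e-12)
        assert event.frailty_change_applied == pytest.approx(d_frailty_2y / 2.0)

        # two-year EQ-5D change with this cycle's annualised frailty change
        d_eq5d_2y = (
            0.500 + 0.002 * 70.0 - 0.040 - 0.010 * 20.0
            - 0.014 * (d_frailty_2y / 2.0) - 0.739 * 0.8 + 0.136 * 0.8**2
        )
        expected_eq5d = 0.8 + d_eq5d_2y / 2.0
        assert ind.eq5d == pytest.approx(expected_eq5d, abs=1e-12)

        # acute non-MA recurrent fall accrues the configured utility loss
        assert ledger["qaly"] == pytest.approx(
            expected_eq5d - rc_scenario.acute_utility_loss["recurrent_non_ma"]
        )
        assert ind.falls_history == "recurrent_non_ma"
        assert ind.age == 71.0

    def test_null_intervention_with_matched_eligibility_gives_identical_run(
        self, small_cohort, rc_scenario, registry
    ):
        """With intervention effect 1.0 the strategies differ only via
        eligibility; aligning eligibility makes trajectories identical."""
        a = dataclasses.replace(rc_scenario, intervention_effect=1.0, label="a")
        b = dataclasses.replace(rc_scenario, intervention_effect=1.0, label="b",
                                strategy="usual_care")
        ra = run_simulation(small_cohort, a, registry, master_seed=5, horizon=3)
        rb = run_simulation(small_cohort, b, registry, master_seed=5, horizon=3)
        left = ra.cycles.drop(columns="scenario")
        right = rb.cycles.drop(columns="scenario")
        assert left.equals(right)

    def test_invalid_probability_is_trapped_not_clamped(
        self, rc_scenario, registry
    ):
        bad = dataclasses.replace(rc_scenario, fall_probability_override=1.5)
        with pytest.raises(InvariantViolation, match="fall probability"):
            run_cycle(make_individual(), bad, registry, np.random.default_rng(0))


class TestRunSimulation:
    def test_horizon_one_equals_single_cycle_pass(
        self, small_cohort, rc_scenario, registry
    ):
        res = run_simulation(small_cohort, rc_scenario, registry, master_seed=3,
                             horizon=1)
        assert (res.cycles["cycle"] == 0).all()
        assert len(res.cycles) == len(small_cohort)
        # independent replay of one individual under the same substream
        ind = small_cohort[17].copy()
        rng = np.random.default_rng([3, ind.id, 0])
        run_cycle(ind, rc_scenario, registry, rng)
        row = res.cycles[res.cycles.id == ind.id].iloc[0]
        assert row["frailty"] == pytest.approx(ind.frailty)
        assert row["eq5d"] == pytest.approx(ind.eq5d)

    def test_alive_count_never_increases(self, small_cohort, rc_scenario, registry):
        res = run_simulation(small_cohort, rc_scenario, registry, master_seed=9,
                             horizon=8)
        counts = res.alive_counts()
        assert (counts.diff().dropna() <= 0).all()

    def test_state_bounds_hold_every_cycle(self, small_cohort, rc_scenario, registry):
        res = run_simulation(small_cohort, rc_scenario, registry, master_seed=9,
                             horizon=8)
        assert res.cycles.frailty.between(0.0, 100.0).all()
        assert res.cycles.eq5d.between(EQ5D_FLOOR, 1.0).all()

    def test_no_rows_and_no_accrual_after_death(
        self, small_cohort, rc_scenario, registry
    ):
        res = run_simulation(small_cohort, rc_scenario, registry, master_seed=9,
                             horizon=8)
        died = res.cycles[~res.cycles.alive]
        assert not died.empty
        for ind_id, death_cycle in died.groupby("id")["cycle"].min().items():
            rows = res.cycles[res.cycles.id == ind_id]
            assert rows["cycle"].max() == death_cycle
            death_row = rows[rows.cycle == death_cycle].iloc[0]
            assert death_row["qaly"] == 0.0
            for col in ("oop_cost", "informal_care_cost", "productivity_value",
                        "intervention_time_cost"):
                assert death_row[col] == 0.0

    def test_input_cohort_not_mutated(self, small_cohort, rc_scenario, registry):
        before = [(i.age, i.frailty, i.alive) for i in small_cohort]
        run_simulation(small_cohort, rc_scenario, registry, master_seed=2, horizon=2)
        after = [(i.age, i.frailty, i.alive) for i in small_cohort]
        assert before == after

    def test_stronger_prevention_never_increases_cumulative_falls(
        self, pooled_cohort, rc_scenario, registry
    ):
        cohort = pooled_cohort[:2000]
        weak = dataclasses.replace(rc_scenario, intervention_effect=1.0, label="weak")
        strong = dataclasses.replace(rc_scenario, intervention_effect=0.7,
                                     label="strong")
        rw = run_simulation(cohort, weak, registry, master_seed=21, horizon=6)
        rs = run_simulation(cohort, strong, registry, master_seed=21, horizon=6)
        falls_weak = (rw.cycles.fall_outcome != "none").sum()
        falls_strong = (rs.cycles.fall_outcome != "none").sum()
        assert falls_strong <= falls_weak

    def test_suppressing_falls_lowers_frailty_raises_utility_lowers_mortality(
        self, pooled_cohort, rc_scenario, registry
    ):
        """Paired run with common random numbers: forcing the fall probability
        to zero must lower mean frailty, raise mean EQ-5D, and lower deaths —
        the falls-frailty feedback loop acts in the documented direction."""
        cohort = pooled_cohort[:1500]
        base = dataclasses.replace(rc_scenario, label="base")
        nofalls = dataclasses.replace(rc_scenario, fall_probability_override=0.0,
                                      label="nofalls")
        rb = run_simulation(cohort, base, registry, master_seed=31, horizon=6)
        rn = run_simulation(cohort, nofalls, registry, master_seed=31, horizon=6)
        last_b = rb.cycles[rb.cycles.cycle == 5]
        last_n = rn.cycles[rn.cycles.cycle == 5]
        assert last_n.frailty.mean() < last_b.frailty.mean()
        assert last_n.eq5d.mean() > last_b.eq5d.mean()
        deaths_b = rb.cycles.fatal_fall.sum() + rb.cycles.died_other_cause.sum()
        deaths_n = rn.cycles.fatal_fall.sum() + rn.cycles.died_other_cause.sum()
        assert deaths_n < deaths_b

    def test_ltc_admission_is_absorbing_and_accrues_ltc_costs(
        self, rc_scenario, registry
    ):
        # High-frailty individual with certain LTC admission
        scenario = dataclasses.replace(
            rc_scenario,
            ltc_annual_probability={"Fit": 0.0, "Mild": 0.0, "Moderate": 1.0,
                                    "Severe": 1.0},
            label="ltc",
        )
        ind = make_individual(frailty=60.0, eq5d=0.3)
        res = run_simulation([ind], scenario, registry, master_seed=4, horizon=6)
        residences = res.cycles.residence.tolist()
        assert "long_term_care" in residences
        first = residences.index("long_term_care")
        assert all(r == "long_term_care" for r in residences[first:])
        # the admission cycle itself accrues as a community year; LTC costs
        # start the cycle after entry
        ltc_rows = res.cycles[(res.cycles.cycle > first) & res.cycles.alive]
        if not ltc_rows.empty:
            share = scenario.ltc_public_share_by_ses[ind.ses_quartile - 1]
            assert np.allclose(ltc_rows.public_cost,
                               scenario.ltc_annual_cost * share)


class TestFatalFallCalibration:
    def test_share_inversion_algebra(self, small_cohort, rc_scenario, registry):
        """The calibrated per-fall fatality probability reproduces the target
        share under the defining approximation s = f p / (f p + m)."""
        targets = {"male_60_69": 0.0076, "female_60_69": 0.0045,
                   "male_70plus": 0.0109, "female_70plus": 0.0096}
        probs = calibrate_fatal_fall_probabilities(
            small_cohort, rc_scenario, registry, targets
        )
        assert set(probs) == set(targets)
        for stratum, p in probs.items():
            assert 0.0 < p < 0.05
        # recompute the implied share from stratum-mean rates and invert back
        from frailsim.engine import _covariates
        from frailsim.population import age_group_of

        for stratum, p in probs.items():
            sex, band = stratum.split("_", 1)
            members = [i for i in small_cohort if i.sex == sex
                       and ((i.age < 70) == (band == "60_69"))]
            f = np.mean([registry.evaluate("falls_incidence", _covariates(i))
                         for i in members])
            m = np.mean([rc_scenario.mortality.rate(age_group_of(i.age), i.sex,
                                                    i.frailty_category)
                         for i in members])
            implied_share = f * p / (f * p + m)
            assert implied_share == pytest.approx(targets[stratum], rel=1e-9)
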
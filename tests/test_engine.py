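"""Cohort engine: single-cycle cascade, lifetime accrual, microsimulation."""

import dataclasses

import numpy as np
import pytest

import depscreen_cea as d
from depscreen_cea.engine import STRATEGIES, CycleState

from _oracles import enumerate_cycle
from conftest import make_schedule

ANNUITY_3PCT_50Y = sum(1.03 ** (-t) for t in range(50))  # 26.5017


@pytest.mark.parametrize("strategy", STRATEGIES, ids=lambda s: f"strategy{s.key}")
@pytest.mark.parametrize("prevalence", [0.0, 0.1, 0.139, 0.5, 1.0])
def test_cycle_matches_decision_tree_enumeration(params, strategy, prevalence):
    """One cohort cycle equals the exhaustive decision-tree expectation."""
    schedule = make_schedule(prevalence, 0.01, 40, 42)
    state = CycleState(age=40)
    nxt, cost, utility = d.cycle_update(state, strategy, params, schedule)
    exp_cost, exp_util, exp_remit = enumerate_cycle(strategy, params, prevalence, 40)
    assert cost == pytest.approx(exp_cost, abs=1e-12)
    assert utility == pytest.approx(exp_util, abs=1e-12)
    assert nxt.remitted == pytest.approx(exp_remit, abs=1e-12)


@pytest.mark.parametrize("fn_fallback", [True, False])
@pytest.mark.parametrize("gate", [True, False])
@pytest.mark.parametrize("cap", [None, 64])
def test_cycle_matches_enumeration_under_switches(params, fn_fallback, gate, cap):
    variant = dataclasses.replace(
        params,
        fn_fallback=fn_fallback,
        screen_positive_treatment_gate=gate,
        productivity_age_cap=cap,
    )
    schedule = make_schedule(0.2, 0.01, 66, 68)
    for strategy in STRATEGIES:
        _, cost, utility = d.cycle_update(CycleState(age=66), strategy, variant, schedule)
        exp_cost, exp_util, _ = enumerate_cycle(strategy, variant, 0.2, 66)
        assert cost == pytest.approx(exp_cost, abs=1e-12)
        assert utility == pytest.approx(exp_util, abs=1e-12)


def test_empty_cascade_when_nobody_is_depressed(params):
    schedule = make_schedule(0.0, 0.01)
    _, cost, utility = d.cycle_update(
        CycleState(age=20), d.strategy_by_key(1), params, schedule
    )
    assert cost == 0.0
    assert utility == params.utilities.u_well


def test_false_positive_cost_closed_form_at_zero_prevalence(params):
    """With nobody depressed, strategy 4 still pays for screening and for
    treating false positives: c_screen + (1-sp)*p_treat*c_cc; utility is
    unchanged because treated healthy people gain and lose nothing."""
    schedule = make_schedule(0.0, 0.01)
    _, cost, utility = d.cycle_update(
        CycleState(age=20), d.strategy_by_key(4), params, schedule
    )
    _, sp = d.combined_characteristics(params.phq2, params.phq9, "two_stage")
    screen = d.screening_cost(params.costs, 1.0 - params.phq2.specificity, "two_stage")
    expected = screen + (1.0 - sp) * 0.61 * 2879.0
    assert cost == pytest.approx(expected, abs=1e-12)
    assert utility == params.utilities.u_well


def test_fully_depressed_cohort_with_perfect_tests(params):
    """Remission = p_treatment_if_diagnosed * p_adequate_cc * p_treatable."""
    perfect = dataclasses.replace(
        params,
        phq2=dataclasses.replace(params.phq2, sensitivity=1.0, specificity=1.0),
        phq9=dataclasses.replace(params.phq9, sensitivity=1.0, specificity=1.0),
    )
    schedule = make_schedule(1.0, 0.01)
    nxt, _, _ = d.cycle_update(CycleState(age=20), d.strategy_by_key(4), perfect, schedule)
    assert nxt.remitted == pytest.approx(0.61 * 0.75 * 0.67)  # 0.3065


def test_state_fractions_conserved_every_cycle(params, schedule):
    for strategy in STRATEGIES:
        result = d.run_strategy(strategy, params, schedule, keep_trace=True)
        totals = (
            result.trace["well"]
            + result.trace["depressed_unremitted"]
            + result.trace["remitted"]
        )
        assert np.allclose(totals, 1.0, atol=1e-12)
        assert (result.trace[["well", "depressed_unremitted", "remitted"]] >= -1e-15).all().all()


def test_cycle_update_requires_schedule_coverage(params):
    schedule = make_schedule(0.1, 0.01, 30, 40)
    with pytest.raises(KeyError, match="age 20"):
        d.cycle_update(CycleState(age=20), d.strategy_by_key(1), params, schedule)


def test_discounted_annuity_closed_form(params):
    """u=1, no deaths, no costs: QALYs = sum of 50 annual discount factors."""
    healthy = dataclasses.replace(
        params, utilities=d.parameters.UtilitySet(1.0, 1.0, 1.0)
    )
    schedule = make_schedule(0.0, 0.0)
    result = d.run_strategy(d.strategy_by_key(1), healthy, schedule)
    assert result.discounted_cost == 0.0
    assert result.discounted_qalys == pytest.approx(ANNUITY_3PCT_50Y, abs=1e-9)
    assert result.discounted_qalys == pytest.approx(26.50, abs=5e-3)

    undiscounted = dataclasses.replace(healthy, discount_rate=0.0)
    result0 = d.run_strategy(d.strategy_by_key(1), undiscounted, schedule)
    assert result0.discounted_qalys == pytest.approx(50.0, abs=1e-9)


def test_totals_nonincreasing_in_discount_rate(params, schedule):
    rates = [0.0, 0.03, 0.07]
    runs = [
        d.run_strategy(
            d.strategy_by_key(4), dataclasses.replace(params, discount_rate=r), schedule
        )
        for r in rates
    ]
    costs = [r.discounted_cost for r in runs]
    qalys = [r.discounted_qalys for r in runs]
    assert costs == sorted(costs, reverse=True)
    assert qalys == sorted(qalys, reverse=True)


def test_collaborative_care_gains_qalys_over_usual_care(base_results):
    """Strategy 4 weakly dominates strategy 2 in QALYs: same screening, but
    adequate treatment is more likely under collaborative care."""
    by_key = {r.strategy.key: r for r in base_results}
    assert by_key[4].discounted_qalys >= by_key[2].discounted_qalys


def test_identical_care_models_collapse_strategy_2_and_4(params, schedule):
    merged = d.with_override(params, "p_adequate_cc", params.pathway.p_adequate_uc)
    merged = d.with_override(merged, "c_treatment_cc", merged.costs.c_treatment_uc)
    r2 = d.run_strategy(d.strategy_by_key(2), merged, schedule)
    r4 = d.run_strategy(d.strategy_by_key(4), merged, schedule)
    assert r2.discounted_cost == pytest.approx(r4.discounted_cost, abs=1e-9)
    assert r2.discounted_qalys == pytest.approx(r4.discounted_qalys, abs=1e-12)


def test_qalys_bounded_by_horizon(base_results, params):
    for result in base_results:
        assert 0 < result.discounted_qalys <= params.horizon_years
        assert result.discounted_cost > 0


def test_microsimulation_converges_to_cohort_expectation(params, schedule):
    """Individual-level simulation means fall within 3 standard errors of
    the cohort expectation for both cost and QALYs."""
    strategy = d.strategy_by_key(4)
    cohort = d.run_strategy(strategy, params, schedule, keep_trace=False)
    micro = d.run_microsimulation(strategy, params, schedule, n_individuals=20_000, seed=42)
    n = len(micro.individual_costs)
    se_cost = micro.individual_costs.std(ddof=1) / np.sqrt(n)
    se_qalys = micro.individual_qalys.std(ddof=1) / np.sqrt(n)
    assert abs(micro.discounted_cost - cohort.discounted_cost) < 3 * se_cost
    assert abs(micro.discounted_qalys - cohort.discounted_qalys) < 3 * se_qalys


def test_microsimulation_deterministic_under_seed(params, flat_schedule):
    a = d.run_microsimulation(d.strategy_by_key(2), params, flat_schedule, 500, seed=7)
    b = d.run_microsimulation(d.strategy_by_key(2), params, flat_schedule, 500, seed=7)
    assert a.discounted_cost == b.discounted_cost
    assert np.array_equal(a.individual_qalys, b.individual_qalys)


def test_single_healthy_individual_annuity(params):
    """n=1, no depression, no costs: QALYs follow the survival-conditional
    annuity determined by the individual's death draw."""
    schedule = make_schedule(0.0, 0.5)
    healthy = dataclasses.replace(params, utilities=d.parameters.UtilitySet(1.0, 1.0, 1.0))
    micro = d.run_microsimulation(d.strategy_by_key(1), healthy, schedule, 1, seed=3)
    assert micro.discounted_cost == 0.0
    # the realised QALY total must equal a partial annuity sum for some
    # integer number of survived cycles
    partials = {round(sum(1.03 ** (-t) for t in range(k)), 9) for k in range(51)}
    assert round(micro.discounted_qalys, 9) in partials
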
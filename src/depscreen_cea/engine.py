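"""Annual-cycle cohort model of screening, treatment and remission.

The cohort is alive or dead; living members are well or depressed in any
given year.  Depression status is re-drawn each cycle from the
age-specific 12-month probability (a prevalence-based, memoryless
model), so a "cycle" walks the full cascade for that year:

1.  depression assignment from the age schedule, less the remission
    feedback carried over from the previous cycle in intervention arms;
2.  detection -- screening arms classify by the joint operating
    characteristics of the cascade (false negatives can still be picked
    up by the background status-quo diagnosis route); the status-quo arm
    diagnoses depressed members with the community diagnosis rate;
3.  treatment entry among the detected (true and false positives alike);
4.  treatment adequacy per care model (collaborative vs usual care);
5.  remission among adequately treated depressed members;
6.  accrual of utility and cost (screening, treatment, lost
    productivity for unremitted depressed person-years);
7.  uniform all-cause mortality;
8.  the remission feedback passed to the next cycle: the excess of this
    arm's remitted fraction of the cohort over what the status-quo
    cascade would have remitted, which lowers next year's probability
    of depression (early treatment reduces relapse).

Cycle length is one year -- the inputs are 12-month prevalences, annual
costs and integer ages -- and no half-cycle correction is applied.
There is no depression-specific excess mortality, false positives incur
treatment cost but no utility change, and inadequately treated or
untreated depression gains nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cascade import combined_characteristics, screening_cost
from .parameters import ModelParameters, REFERENCE_SCREENING_COST
from .synthetic_inputs import AgeSchedule

__all__ = [
    "Strategy",
    "STRATEGIES",
    "strategy_by_key",
    "CycleState",
    "StrategyResult",
    "cycle_update",
    "run_strategy",
    "run_all_strategies",
    "run_microsimulation",
]


@dataclass(frozen=True)
class Strategy:
    """One arm: a screening mode crossed with a care model."""

    key: int
    label: str
    screening: str  # "none" | "two_stage" | "phq9_only"
    care: str  # "uc" | "cc"


STRATEGIES: tuple[Strategy, ...] = (
    Strategy(1, "No screening; usual care", "none", "uc"),
    Strategy(2, "PHQ-2/9 screening; usual care", "two_stage", "uc"),
    Strategy(3, "PHQ-9 screening; usual care", "phq9_only", "uc"),
    Strategy(4, "PHQ-2/9 screening; collaborative care", "two_stage", "cc"),
    Strategy(5, "PHQ-9 screening; collaborative care", "phq9_only", "cc"),
)


def strategy_by_key(key: int) -> Strategy:
    for strategy in STRATEGIES:
        if strategy.key == key:
            return strategy
    raise KeyError(f"no strategy with key {key}; known keys 1-5")


@dataclass
class CycleState:
    """End-of-cycle composition of the living cohort."""

    age: int
    well: float = 1.0
    depressed_unremitted: float = 0.0
    remitted: float = 0.0
    survival: float = 1.0
    remission_feedback: float = 0.0

    def __post_init__(self) -> None:
        for name in ("well", "depressed_unremitted", "remitted"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"state fraction {name} is negative")
        total = self.well + self.depressed_unremitted + self.remitted
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions must sum to 1, got {total!r}")
        if not (0.0 <= self.survival <= 1.0):
            raise ValueError(f"survival must lie in [0, 1], got {self.survival!r}")


@dataclass
class StrategyResult:
    """Discounted lifetime totals for one arm, with an auditable trace."""

    strategy: Strategy
    discounted_cost: float
    discounted_qalys: float
    trace: Optional[pd.DataFrame] = None
    individual_costs: Optional[np.ndarray] = None
    individual_qalys: Optional[np.ndarray] = None


@dataclass(frozen=True)
class _ArmRates:
    """Age-independent cascade rates for one strategy under one input set."""

    screening: str
    se2: float  # PHQ-2 stage, for the positive-rate cost adjustment
    sp2: float
    entry_dep: float  # P(treatment entry | depressed)
    entry_well: float  # P(treatment entry | well) -- false positives
    remit_given_entry: float  # P(remission | treatment entry, depressed)
    remit_dep: float  # P(remission | depressed)
    r_status_quo: float  # P(remission | depressed) under the status-quo cascade
    c_treat: float
    screen_fixed: float  # per-person screening cost excluding the PHQ-9 review
    screen_per_positive: float  # physician PHQ-9 review cost per PHQ-2 positive


def _arm_rates(strategy: Strategy, params: ModelParameters) -> _ArmRates:
    pw = params.pathway
    gate = pw.p_treatment_if_diagnosed
    r_status_quo = pw.p_diagnosis_status_quo * gate * pw.p_adequate_uc * pw.p_treatable
    adequate = pw.p_adequate_cc if strategy.care == "cc" else pw.p_adequate_uc
    c_treat = (
        params.costs.c_treatment_cc if strategy.care == "cc" else params.costs.c_treatment_uc
    )
    scale = params.costs.c_screening_two_stage / REFERENCE_SCREENING_COST

    se2 = sp2 = 0.0
    screen_fixed = screen_per_positive = 0.0
    if strategy.screening == "none":
        entry_dep = pw.p_diagnosis_status_quo * gate
        entry_well = 0.0
    else:
        se, sp = combined_characteristics(params.phq2, params.phq9, strategy.screening)
        screen_gate = gate if params.screen_positive_treatment_gate else 1.0
        entry_dep = se * screen_gate
        if params.fn_fallback:
            entry_dep += (1.0 - se) * pw.p_diagnosis_status_quo * gate
        entry_well = (1.0 - sp) * screen_gate
        if strategy.screening == "two_stage":
            se2, sp2 = params.phq2.sensitivity, params.phq2.specificity
            screen_fixed = scale * screening_cost(params.costs, 0.0, "two_stage")
            screen_per_positive = scale * (
                params.costs.wage_gp * params.costs.minutes_gp_phq9 / 60.0
            )
        else:
            screen_fixed = scale * screening_cost(params.costs, 0.0, "phq9_only")

    remit_given_entry = adequate * pw.p_treatable
    return _ArmRates(
        screening=strategy.screening,
        se2=se2,
        sp2=sp2,
        entry_dep=entry_dep,
        entry_well=entry_well,
        remit_given_entry=remit_given_entry,
        remit_dep=entry_dep * remit_given_entry,
        r_status_quo=r_status_quo,
        c_treat=c_treat,
        screen_fixed=screen_fixed,
        screen_per_positive=screen_per_positive,
    )


def _step(
    strategy: Strategy,
    rates: _ArmRates,
    params: ModelParameters,
    age: int,
    p_dep_raw: float,
    feedback: float,
):
    """One annual cycle for the living cohort; returns accrual and carry-overs.

    ``p_dep_raw`` is the schedule probability after the depression scale
    factor but before remission feedback.
    """
    if strategy.key == 1 or params.feedback_policy == "none":
        d = p_dep_raw
    elif params.feedback_policy == "proportional":
        d = p_dep_raw * (1.0 - min(1.0, feedback))
    else:  # incremental_remissions: absolute reduction in the probability
        d = max(0.0, p_dep_raw - feedback)
    well = 1.0 - d
    remit = d * rates.remit_dep

    u = params.utilities
    utility = (
        well * u.u_well + (d - remit) * u.u_depressed + remit * u.u_remission
    )

    cost = (d * rates.entry_dep + well * rates.entry_well) * rates.c_treat
    if rates.screening == "two_stage":
        p2pos = d * rates.se2 + well * (1.0 - rates.sp2)
        cost += rates.screen_fixed + p2pos * rates.screen_per_positive
    elif rates.screening == "phq9_only":
        cost += rates.screen_fixed
    cap = params.productivity_age_cap
    if cap is None or age <= cap:
        cost += (d - remit) * params.costs.c_productivity_total

    if strategy.key == 1:
        feedback_next = 0.0
    elif params.feedback_policy == "proportional":
        feedback_next = max(0.0, rates.remit_dep - rates.r_status_quo)
    else:
        feedback_next = max(0.0, remit - p_dep_raw * rates.r_status_quo)
    return d, remit, cost, utility, feedback_next


def cycle_update(
    state: CycleState,
    strategy: Strategy,
    params: ModelParameters,
    schedule: AgeSchedule,
) -> tuple[CycleState, float, float]:
    """Advance one annual cycle from ``state.age``.

    Returns the next state together with this cycle's expected cost (USD
    per person alive at the start of the cycle) and utility (HRQL-years).
    """
    rates = _arm_rates(strategy, params)
    p_dep_raw = min(1.0, schedule.p_depression(state.age) * params.p_depression_scale)
    d, remit, cost, utility, feedback_next = _step(
        strategy, rates, params, state.age, p_dep_raw, state.remission_feedback
    )
    next_state = CycleState(
        age=state.age + 1,
        well=1.0 - d,
        depressed_unremitted=d - remit,
        remitted=remit,
        survival=state.survival * (1.0 - schedule.p_death(state.age)),
        remission_feedback=feedback_next,
    )
    return next_state, cost, utility


def run_strategy(
    strategy: Strategy,
    params: ModelParameters,
    schedule: AgeSchedule,
    keep_trace: bool = True,
) -> StrategyResult:
    """Run the cohort model for one arm over the full age horizon.

    Cycle ``t`` (age ``age_start + t``) contributes its expected cost and
    utility weighted by survival to the start of the cycle and by the
    discount factor ``(1 + r)^-t``.
    """
    if not schedule.covers(params.age_start, params.age_end):
        raise ValueError(
            f"schedule does not cover ages {params.age_start}-{params.age_end - 1}"
        )
    ages, p_dep, p_death = schedule.arrays(params.age_start, params.age_end)
    rates = _arm_rates(strategy, params)
    disc = 1.0 / (1.0 + params.discount_rate)
    scale = params.p_depression_scale

    total_cost = 0.0
    total_qalys = 0.0
    survival = 1.0
    weight_disc = 1.0
    feedback = 0.0
    rows: list[tuple] = []
    for t in range(len(ages)):
        age = int(ages[t])
        p_dep_raw = min(1.0, p_dep[t] * scale)
        d, remit, cost, utility, feedback = _step(
            strategy, rates, params, age, p_dep_raw, feedback
        )
        weight = survival * weight_disc
        total_cost += weight * cost
        total_qalys += weight * utility
        if keep_trace:
            rows.append(
                (age, 1.0 - d, d - remit, remit, survival, cost, utility,
                 weight * cost, weight * utility)
            )
        survival *= 1.0 - p_death[t]
        weight_disc *= disc

    trace = None
    if keep_trace:
        trace = pd.DataFrame(
            rows,
            columns=[
                "age",
                "well",
                "depressed_unremitted",
                "remitted",
                "survival",
                "cycle_cost",
                "cycle_utility",
                "discounted_cost",
                "discounted_utility",
            ],
        )
    return StrategyResult(strategy, total_cost, total_qalys, trace)


def run_all_strategies(
    params: ModelParameters, schedule: AgeSchedule, keep_trace: bool = False
) -> list[StrategyResult]:
    return [run_strategy(s, params, schedule, keep_trace) for s in STRATEGIES]


def run_microsimulation(
    strategy: Strategy,
    params: ModelParameters,
    schedule: AgeSchedule,
    n_individuals: int,
    seed: int,
) -> StrategyResult:
    """First-order (individual-level) Monte Carlo walk through the cascade.

    Each simulated person draws depression status, treatment entry,
    remission and survival as Bernoulli events with the same per-cycle
    probabilities the cohort model uses, so the expectation converges to
    :func:`run_strategy`.  The cohort run is authoritative; this surface
    exists to cross-validate it and to expose between-individual
    variability.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals!r}")
    ages, p_dep, p_death = schedule.arrays(params.age_start, params.age_end)
    rates = _arm_rates(strategy, params)
    disc = 1.0 / (1.0 + params.discount_rate)
    u = params.utilities
    cap = params.productivity_age_cap
    c_prod = params.costs.c_productivity_total

    # Deterministic per-cycle depression probability (incl. feedback), and
    # per-person screening cost, from the cohort recursion.
    d_t = np.empty(len(ages))
    screen_t = np.zeros(len(ages))
    feedback = 0.0
    for t in range(len(ages)):
        p_dep_raw = min(1.0, p_dep[t] * params.p_depression_scale)
        d, _remit, _cost, _util, feedback = _step(
            strategy, rates, params, int(ages[t]), p_dep_raw, feedback
        )
        d_t[t] = d
        if rates.screening == "two_stage":
            p2pos = d * rates.se2 + (1.0 - d) * (1.0 - rates.sp2)
            screen_t[t] = rates.screen_fixed + p2pos * rates.screen_per_positive
        elif rates.screening == "phq9_only":
            screen_t[t] = rates.screen_fixed

    rng = np.random.default_rng(seed)
    n = int(n_individuals)
    alive = np.ones(n, dtype=bool)
    costs = np.zeros(n)
    qalys = np.zeros(n)
    weight = 1.0
    for t in range(len(ages)):
        age = int(ages[t])
        depressed = rng.random(n) < d_t[t]
        entry_p = np.where(depressed, rates.entry_dep, rates.entry_well)
        entered = rng.random(n) < entry_p
        remitted = depressed & entered & (rng.random(n) < rates.remit_given_entry)

        utility = np.where(
            depressed, np.where(remitted, u.u_remission, u.u_depressed), u.u_well
        )
        cycle_cost = screen_t[t] + entered * rates.c_treat
        if cap is None or age <= cap:
            cycle_cost = cycle_cost + (depressed & ~remitted) * c_prod

        costs[alive] += weight * cycle_cost[alive]
        qalys[alive] += weight * utility[alive]
        alive &= rng.random(n) >= p_death[t]
        weight *= disc

    return StrategyResult(
        strategy,
        discounted_cost=float(costs.mean()),
        discounted_qalys=float(qalys.mean()),
        trace=None,
        individual_costs=costs,
        individual_qalys=qalys,
    )
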
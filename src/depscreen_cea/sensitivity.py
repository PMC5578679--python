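"""One-way and probabilistic sensitivity analysis.

One-way analysis re-runs the full model with a single input at its low
or high bound (cut-off parameters swap in the matching sensitivity /
specificity pair; the lost-productivity age cap swaps between "all ages"
and "working ages only") and reports the incremental cost, incremental
QALYs and ICER of two-stage screening plus collaborative care against
the status quo.

The probabilistic analysis draws every registered parameter
independently from its triangular(low, mode, high) distribution, runs
all five strategies per draw, and summarises the simulation as a 95%
plausible interval for the ICER, a cost-effectiveness acceptability
curve (CEAC), and the expected value of perfect information (EVPI).
Parameters are sampled independently -- the published inputs carry no
correlation structure -- and probability draws are clipped to [0, 1] as
a guard.

The plausible interval is read off order statistics of the draws ranked
from most to least favourable on the cost-effectiveness plane:
cost-saving draws (money saved, QALYs gained) rank best, then draws in
order of increasing ICER, then draws that cost more for no gain.  This
avoids the undefined mean-of-ratios problem, and a bound that falls
among the cost-saving draws is reported as "cost-saving" rather than as
a meaningless negative ratio.  Ties are broken by incremental net
monetary benefit at the reference willingness-to-pay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cea import DOMINANT, icer, nmb
from .engine import STRATEGIES, run_all_strategies, run_strategy, strategy_by_key
from .parameters import (
    ModelParameters,
    TriangularParam,
    UnknownParameterError,
    with_override,
)
from .synthetic_inputs import AgeSchedule

__all__ = [
    "OneWayResult",
    "one_way",
    "one_way_table",
    "ONE_WAY_PARAMETERS",
    "sample_triangular",
    "PSAOutput",
    "run_psa",
    "export_scatter",
]

#: Probability-like registry entries whose draws are clipped to [0, 1].
_PROBABILITY_PARAMS = {
    "u_depressed",
    "u_remission",
    "p_treatable",
    "p_diagnosis_status_quo",
    "p_treatment_if_diagnosed",
    "p_adequate_cc",
    "p_adequate_uc",
    "se_phq2",
    "sp_phq2",
    "se_phq9",
    "sp_phq9",
}


@dataclass
class Incremental:
    """Strategy 4 vs strategy 1: cost and QALY increments with the ICER."""

    delta_cost: float
    delta_qalys: float
    icer: Union[float, str]


@dataclass
class OneWayResult:
    parameter: str
    base: Incremental
    at_high: Incremental
    at_low: Incremental
    high_value: object = None
    low_value: object = None


def _incremental(params: ModelParameters, schedule: AgeSchedule) -> Incremental:
    ref = run_strategy(strategy_by_key(1), params, schedule, keep_trace=False)
    arm = run_strategy(strategy_by_key(4), params, schedule, keep_trace=False)
    dc = arm.discounted_cost - ref.discounted_cost
    de = arm.discounted_qalys - ref.discounted_qalys
    return Incremental(dc, de, icer(dc, de))


def _one_way_bounds(params: ModelParameters, name: str):
    """(high value, low value) for a registered one-way parameter."""
    if name == "phq2_cutoff":
        return max(params.phq2.alternates), min(params.phq2.alternates)
    if name == "phq9_cutoff":
        return max(params.phq9.alternates), min(params.phq9.alternates)
    if name == "productivity_age_cap":
        # High: productivity losses at every age; low: working ages only.
        return None, 64
    try:
        tri = params.triangulars[name]
    except KeyError:
        raise UnknownParameterError(
            f"no high/low bounds registered for parameter {name!r}"
        ) from None
    return tri.high, tri.low


def one_way(params: ModelParameters, schedule: AgeSchedule, name: str) -> OneWayResult:
    """Full-model one-way sensitivity analysis for a single parameter."""
    high, low = _one_way_bounds(params, name)
    base = _incremental(params, schedule)
    at_high = _incremental(with_override(params, name, high), schedule)
    at_low = _incremental(with_override(params, name, low), schedule)
    return OneWayResult(name, base, at_high, at_low, high, low)


#: Parameters reported by the one-way table, in presentation order.
ONE_WAY_PARAMETERS = (
    "c_treatment_cc",
    "c_treatment_uc",
    "c_screening",
    "c_productivity_total",
    "productivity_age_cap",
    "u_depressed",
    "u_remission",
    "p_treatable",
    "p_diagnosis_status_quo",
    "p_treatment_if_diagnosed",
    "p_adequate_cc",
    "p_adequate_uc",
    "phq2_cutoff",
    "phq9_cutoff",
    "p_depression_scale",
)


def one_way_table(
    params: ModelParameters,
    schedule: AgeSchedule,
    names: Sequence[str] = ONE_WAY_PARAMETERS,
) -> pd.DataFrame:
    """One row per parameter: increments and ICERs at the high and low bounds."""
    records = []
    for name in names:
        res = one_way(params, schedule, name)
        records.append(
            {
                "parameter": name,
                "high_value": res.high_value,
                "low_value": res.low_value,
                "inc_cost_high": res.at_high.delta_cost,
                "inc_cost_low": res.at_low.delta_cost,
                "inc_qalys_high": res.at_high.delta_qalys,
                "inc_qalys_low": res.at_low.delta_qalys,
                "icer_high": res.at_high.icer,
                "icer_low": res.at_low.icer,
            }
        )
    return pd.DataFrame.from_records(records)


def sample_triangular(p: TriangularParam, u: float) -> float:
    """Inverse-CDF draw from triangular(low, mode=base, high) at quantile ``u``."""
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"u must lie in [0, 1], got {u!r}")
    width = p.high - p.low
    if width == 0.0:
        return p.base
    f_mode = (p.base - p.low) / width
    if u < f_mode:
        return p.low + np.sqrt(u * width * (p.base - p.low))
    return p.high - np.sqrt((1.0 - u) * width * (p.high - p.base))


@dataclass
class IntervalBound:
    """One end of the plausible interval: an ICER or a quadrant label."""

    delta_cost: float
    delta_qalys: float
    icer: Union[float, str]

    @property
    def label(self) -> str:
        if self.icer == DOMINANT:
            return "cost-saving"
        if isinstance(self.icer, str):
            return self.icer
        return f"{self.icer:,.0f}"


@dataclass
class PSAOutput:
    draws: pd.DataFrame
    ceac: pd.DataFrame  # columns wtp, p_cost_effective
    evpi: pd.DataFrame  # columns wtp, evpi
    plausible_interval: tuple[IntervalBound, IntervalBound]
    seed: int
    wtp_reference: float
    strategy_keys: tuple[int, ...] = field(
        default_factory=lambda: tuple(s.key for s in STRATEGIES)
    )

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def run_psa(
    params: ModelParameters,
    schedule: AgeSchedule,
    n_draws: int = 10_000,
    seed: int = 20150831,
    wtp_grid: Optional[np.ndarray] = None,
    sampled: Optional[Sequence[str]] = None,
) -> PSAOutput:
    """Triangular-distribution Monte Carlo over all registered parameters.

    Each draw perturbs every sampled parameter, runs all five strategies
    and records their discounted costs and QALYs plus the increments of
    two-stage screening + collaborative care (strategy 4) over the
    status quo (strategy 1).  Reproducible for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws!r}")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 50_001.0, 1_000.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size and wtp_grid.min() < 0:
        raise ValueError("wtp grid must be nonnegative")
    names = list(sampled if sampled is not None else sorted(params.triangulars))
    for name in names:
        if name not in params.triangulars:
            raise UnknownParameterError(f"no triangular registered for {name!r}")

    rng = np.random.default_rng(seed)
    n_strat = len(STRATEGIES)
    costs = np.empty((n_draws, n_strat))
    qalys = np.empty((n_draws, n_strat))
    sampled_values = np.empty((n_draws, len(names)))
    for i in range(n_draws):
        draw_params = params
        for j, name in enumerate(names):
            value = sample_triangular(params.triangulars[name], rng.random())
            if name in _PROBABILITY_PARAMS:
                value = min(1.0, max(0.0, value))
            sampled_values[i, j] = value
            draw_params = with_override(draw_params, name, value)
        for k, result in enumerate(run_all_strategies(draw_params, schedule)):
            costs[i, k] = result.discounted_cost
            qalys[i, k] = result.discounted_qalys

    delta_cost = costs[:, 3] - costs[:, 0]
    delta_qalys = qalys[:, 3] - qalys[:, 0]

    draws = pd.DataFrame(sampled_values, columns=names)
    for k, strategy in enumerate(STRATEGIES):
        draws[f"cost_{strategy.key}"] = costs[:, k]
        draws[f"qalys_{strategy.key}"] = qalys[:, k]
    draws["delta_cost"] = delta_cost
    draws["delta_qalys"] = delta_qalys

    # CEAC: probability the intervention beats the status quo at each wtp.
    ceac_p = [
        float(np.mean(w * delta_qalys - delta_cost > 0)) for w in wtp_grid
    ]
    ceac = pd.DataFrame({"wtp": wtp_grid, "p_cost_effective": ceac_p})

    # EVPI: value of resolving all uncertainty before choosing among arms.
    # The max() identity guarantees nonnegativity; clip float roundoff.
    evpi_values = []
    for w in wtp_grid:
        benefit = w * qalys - costs
        evpi_values.append(
            max(0.0, float(np.mean(benefit.max(axis=1)) - benefit.mean(axis=0).max()))
        )
    evpi = pd.DataFrame({"wtp": wtp_grid, "evpi": evpi_values})

    # Plausible interval from order statistics on the cost-effectiveness
    # plane: cost-saving draws first, then increasing ICER, then draws
    # with no QALY gain; ΔNMB at the reference wtp breaks ties.
    with np.errstate(divide="ignore"):
        ratio = np.where(delta_qalys > 0, delta_cost / np.where(delta_qalys > 0, delta_qalys, 1.0), np.inf)
    rank_key = np.where((delta_qalys > 0) & (delta_cost < 0), -np.inf, ratio)
    ref_nmb = params.wtp_reference * delta_qalys - delta_cost
    order = np.lexsort((-ref_nmb, rank_key))  # best draw first
    lo_idx = order[int(0.025 * (n_draws - 1))]  # most favourable bound
    hi_idx = order[int(round(0.975 * (n_draws - 1)))]  # least favourable bound
    lower = IntervalBound(
        float(delta_cost[lo_idx]), float(delta_qalys[lo_idx]),
        icer(float(delta_cost[lo_idx]), float(delta_qalys[lo_idx])),
    )
    upper = IntervalBound(
        float(delta_cost[hi_idx]), float(delta_qalys[hi_idx]),
        icer(float(delta_cost[hi_idx]), float(delta_qalys[hi_idx])),
    )
    return PSAOutput(
        draws=draws,
        ceac=ceac,
        evpi=evpi,
        plausible_interval=(lower, upper),
        seed=seed,
        wtp_reference=params.wtp_reference,
    )


def export_scatter(
    psa: PSAOutput, path: str | Path, plot: bool = False
) -> pd.DataFrame:
    """Write the incremental cost-effectiveness scatter (one row per draw).

    Writes a CSV of (incremental effectiveness, incremental cost) pairs;
    with ``plot=True`` an accompanying PNG is rendered next to it.
    """
    if psa.n_draws == 0:
        raise ValueError("PSA output contains no draws")
    path = Path(path)
    table = psa.draws[["delta_qalys", "delta_cost"]].rename(
        columns={
            "delta_qalys": "incremental_effectiveness_qalys",
            "delta_cost": "incremental_cost_usd",
        }
    )
    table.to_csv(path, index=False)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(
            table["incremental_effectiveness_qalys"],
            table["incremental_cost_usd"],
            s=4,
            alpha=0.3,
        )
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("Incremental effectiveness (QALYs)")
        ax.set_ylabel("Incremental cost (USD)")
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=150)
        plt.close(fig)
    return table
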
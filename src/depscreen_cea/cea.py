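"""Fully incremental cost-effectiveness analysis.

Strategies are ordered by effectiveness and compared sequentially:
equal-effectiveness ties keep only the cheapest arm, a first-ranked arm
that is beaten outright by a cheaper, more effective one is dominated,
and any arm whose ICER against its predecessor exceeds the ICER of the
next, more effective arm is removed by extended dominance (a mixture of
its neighbours would deliver more health for less money).  The process
repeats until the ICERs along the surviving frontier increase strictly
with effectiveness.

Increments recorded for removed strategies are the raw differences
against the strategy that preceded them at the moment of removal, which
is how fully incremental tables are conventionally printed; frontier
strategies report increments against the previous frontier member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "icer",
    "nmb",
    "FrontierRow",
    "FrontierTable",
    "incremental_analysis",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"

ON_FRONTIER = "on_frontier"
STATUS_DOMINATED = "dominated"
STATUS_EXT_DOMINATED = "extendedly_dominated"


def icer(delta_cost: float, delta_qalys: float) -> Union[float, str]:
    """Incremental cost-effectiveness ratio, or a quadrant marker.

    ``dominant`` -- saves money and gains QALYs; ``dominated`` -- costs
    more for no gain; ``undefined`` -- cheaper and no better (a trade-off
    the ratio alone cannot rank).
    """
    if delta_qalys > 0:
        if delta_cost < 0:
            return DOMINANT
        return delta_cost / delta_qalys
    if delta_cost > 0:
        return DOMINATED
    return UNDEFINED


def nmb(cost: float, qalys: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` (USD/QALY)."""
    if wtp < 0:
        raise ValueError(f"wtp must be nonnegative, got {wtp!r}")
    return wtp * qalys - cost


def round_half_away(value: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)


@dataclass
class FrontierRow:
    strategy: object  # identifier (Strategy or any hashable label)
    cost: float
    qalys: float
    status: str = ON_FRONTIER
    comparator: Optional[object] = None
    inc_cost: Optional[float] = None
    inc_qalys: Optional[float] = None
    icer: Optional[Union[float, str]] = None


@dataclass
class FrontierTable:
    rows: list[FrontierRow] = field(default_factory=list)

    @property
    def frontier(self) -> list[FrontierRow]:
        return [r for r in self.rows if r.status == ON_FRONTIER]

    def row(self, strategy) -> FrontierRow:
        for r in self.rows:
            if r.strategy == strategy:
                return r
        raise KeyError(f"strategy {strategy!r} not in table")

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            shown_icer = r.icer
            if isinstance(shown_icer, float):
                shown_icer = round_half_away(shown_icer)
            records.append(
                {
                    "strategy": getattr(r.strategy, "label", r.strategy),
                    "cost": round(r.cost, 2),
                    "qalys": round(r.qalys, 2),
                    "incremental_cost": None if r.inc_cost is None else round(r.inc_cost, 2),
                    "incremental_qalys": None if r.inc_qalys is None else round(r.inc_qalys, 2),
                    "icer": shown_icer,
                    "status": r.status,
                    "comparator": getattr(r.comparator, "label", r.comparator),
                }
            )
        return pd.DataFrame.from_records(records)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _icer_value(delta_cost: float, delta_qalys: float) -> float:
    """ICER as an orderable number: cost-saving counts as -inf."""
    if delta_qalys > 0:
        return delta_cost / delta_qalys if delta_cost >= 0 else -math.inf
    return math.inf


def incremental_analysis(
    results: Sequence[tuple[object, float, float]],
) -> FrontierTable:
    """Fully incremental analysis over (strategy, cost, qalys) triples.

    Accepts :class:`~depscreen_cea.engine.StrategyResult` objects or raw
    triples.  Returns every input strategy with its dominance status,
    increments and ICER.
    """
    entries = []
    for item in results:
        if hasattr(item, "discounted_cost"):
            entries.append((item.strategy, float(item.discounted_cost), float(item.discounted_qalys)))
        else:
            name, cost, qalys = item
            entries.append((name, float(cost), float(qalys)))
    if not entries:
        raise ValueError("at least one strategy is required")
    idents = [e[0] for e in entries]
    if len(set(map(repr, idents))) != len(idents):
        raise ValueError("duplicate strategy identifiers")
    for name, cost, qalys in entries:
        if not (math.isfinite(cost) and math.isfinite(qalys)):
            raise ValueError(f"non-finite cost/qalys for strategy {name!r}")

    rows = {id(e): FrontierRow(strategy=e[0], cost=e[1], qalys=e[2]) for e in entries}
    # Effectiveness order; among equally effective arms the cheaper first.
    surviving = sorted(entries, key=lambda e: (e[2], e[1]))

    def mark_removed(entry, prev, status):
        row = rows[id(entry)]
        row.status = status
        if prev is not None:
            row.comparator = prev[0]
            row.inc_cost = entry[1] - prev[1]
            row.inc_qalys = entry[2] - prev[2]
            row.icer = icer(row.inc_cost, row.inc_qalys)

    while len(surviving) > 1:
        removal = None
        # Equal-effectiveness ties: costlier arm is dominated outright.
        for k in range(1, len(surviving)):
            prev, cur = surviving[k - 1], surviving[k]
            if cur[2] == prev[2] and cur[1] > prev[1]:
                removal = (k, prev, STATUS_DOMINATED)
                break
        if removal is None:
            # Least effective arm beaten outright by a cheaper, better one.
            first, second = surviving[0], surviving[1]
            if second[2] > first[2] and second[1] <= first[1]:
                removal = (0, second, STATUS_DOMINATED)
        if removal is None:
            # Extended dominance: ICER against the predecessor exceeds the
            # ICER of the next, more effective arm.
            vals = [
                _icer_value(surviving[k][1] - surviving[k - 1][1],
                            surviving[k][2] - surviving[k - 1][2])
                for k in range(1, len(surviving))
            ]
            for k in range(1, len(surviving) - 1):
                if vals[k - 1] > vals[k]:
                    removal = (k, surviving[k - 1], STATUS_EXT_DOMINATED)
                    break
        if removal is None:
            break
        index, comparator, status = removal
        mark_removed(surviving[index], comparator, status)
        surviving.pop(index)

    prev = None
    for entry in surviving:
        row = rows[id(entry)]
        row.status = ON_FRONTIER
        if prev is not None:
            row.comparator = prev[0]
            row.inc_cost = entry[1] - prev[1]
            row.inc_qalys = entry[2] - prev[2]
            row.icer = icer(row.inc_cost, row.inc_qalys)
        prev = entry

    ordered = sorted(rows.values(), key=lambda r: (r.qalys, r.cost))
    return FrontierTable(rows=ordered)
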
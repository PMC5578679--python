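"""Synthetic age-specific schedules of depression and mortality.

The model consumes one row per year of age with the 12-month probability
of depression in the primary-care population and the annual all-cause
probability of death.  Published analyses take these from a national
life table and a population health survey; those exact tables are not
redistributable, so this module generates realistic stand-ins:

* mortality follows a Gompertz hazard (exponentially increasing adult
  force of mortality), with defaults calibrated so that discounted
  survival time from age 20 to 70 at a 3% rate falls in the documented
  25-27 year window;
* depression prevalence is step-constant over age bands, multiplied by
  the primary-care enrichment factor (primary-care patients carry 1.74
  times the general-population prevalence).

The band prevalences shipped here are synthetic stand-ins for the NYC
HANES 2013-2014 age-group estimates, chosen jointly with the mortality
defaults so the status-quo arm of the model reproduces its published
discounted totals.  Users with access to real schedules can bypass the
generators entirely via :func:`read_schedule`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeSchedule",
    "PrevalenceBand",
    "DEFAULT_GOMPERTZ_LEVEL",
    "DEFAULT_GOMPERTZ_SLOPE",
    "DEFAULT_PREVALENCE_BANDS",
    "generate_mortality_schedule",
    "generate_depression_schedule",
    "default_schedule",
    "read_schedule",
    "write_schedule",
    "discounted_survival",
]

SCHEDULE_COLUMNS = ("age", "p_depression", "p_death")

#: Gompertz hazard at the first adult age (per year).
DEFAULT_GOMPERTZ_LEVEL = 3.633e-4
#: Exponential growth rate of the hazard with age (per year).
DEFAULT_GOMPERTZ_SLOPE = 0.058


@dataclass(frozen=True)
class PrevalenceBand:
    """General-population 12-month depression prevalence over an age range."""

    age_lo: int
    age_hi: int  # inclusive
    prevalence: float

    def __post_init__(self) -> None:
        if self.age_lo > self.age_hi:
            raise ValueError(f"band ages out of order: ({self.age_lo}, {self.age_hi})")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError(
                f"band prevalence must lie in [0, 1], got {self.prevalence!r}"
            )


#: Synthetic stand-ins for survey age-group prevalences (general population,
#: 12-month).  Values rise through midlife and fall at older ages; the level
#: is calibrated as described in the module docstring.
DEFAULT_PREVALENCE_BANDS = (
    PrevalenceBand(20, 29, 0.0806),
    PrevalenceBand(30, 39, 0.0865),
    PrevalenceBand(40, 49, 0.0953),
    PrevalenceBand(50, 59, 0.1002),
    PrevalenceBand(60, 70, 0.0865),
)


@dataclass(eq=False)
class AgeSchedule:
    """Per-age probabilities of depression and death over a contiguous range."""

    table: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SCHEDULE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"schedule is missing column(s): {missing}")
        table = self.table.loc[:, list(SCHEDULE_COLUMNS)].reset_index(drop=True)
        ages = table["age"].to_numpy()
        if len(ages) == 0:
            raise ValueError("schedule is empty")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
            gaps = sorted(set(range(int(ages.min()), int(ages.max()) + 1)) - set(ages))
            raise ValueError(f"schedule ages must be contiguous; missing ages {gaps}")
        for col in ("p_depression", "p_death"):
            values = table[col].to_numpy(float)
            bad = np.where((values < 0) | (values > 1))[0]
            if bad.size:
                age = int(table["age"].iloc[bad[0]])
                raise ValueError(
                    f"{col} out of [0, 1] at age {age}: {values[bad[0]]!r}"
                )
        p_death = table["p_death"].to_numpy(float)
        if np.any(np.diff(p_death) < -1e-12):
            age = int(table["age"].iloc[int(np.where(np.diff(p_death) < -1e-12)[0][0]) + 1])
            raise ValueError(f"p_death must be nondecreasing with age; decrease at age {age}")
        object.__setattr__(self, "table", table)
        object.__setattr__(
            self, "_index", {int(a): i for i, a in enumerate(table["age"])}
        )

    @property
    def ages(self) -> np.ndarray:
        return self.table["age"].to_numpy()

    def covers(self, age_start: int, age_end: int) -> bool:
        return age_start in self._index and (age_end - 1) in self._index

    def p_depression(self, age: int) -> float:
        return float(self.table["p_depression"].iloc[self._lookup(age)])

    def p_death(self, age: int) -> float:
        return float(self.table["p_death"].iloc[self._lookup(age)])

    def _lookup(self, age: int) -> int:
        try:
            return self._index[int(age)]
        except KeyError:
            raise KeyError(
                f"age {age} not covered by schedule "
                f"({int(self.ages[0])}-{int(self.ages[-1])})"
            ) from None

    def arrays(self, age_start: int, age_end: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ages, p_depression, p_death) for cycles at ages [age_start, age_end)."""
        i0 = self._lookup(age_start)
        i1 = self._lookup(age_end - 1) + 1
        sub = self.table.iloc[i0:i1]
        return (
            sub["age"].to_numpy(int),
            sub["p_depression"].to_numpy(float),
            sub["p_death"].to_numpy(float),
        )


def generate_mortality_schedule(
    age_start: int = 20,
    age_end: int = 70,
    gompertz_level: float = DEFAULT_GOMPERTZ_LEVEL,
    gompertz_slope: float = DEFAULT_GOMPERTZ_SLOPE,
) -> np.ndarray:
    """Annual death probabilities for ages ``age_start..age_end`` (inclusive).

    ``p_death(a) = 1 - exp(-level * exp(slope * (a - age_start)))``, the
    discrete-time death probability under a Gompertz hazard, clipped to
    [0, 1].  A zero level is the no-mortality limit.
    """
    if age_start >= age_end:
        raise ValueError(f"age_start ({age_start}) must be below age_end ({age_end})")
    if gompertz_level < 0 or gompertz_slope < 0:
        raise ValueError(
            f"Gompertz parameters must be nonnegative, got level={gompertz_level!r}, "
            f"slope={gompertz_slope!r}"
        )
    ages = np.arange(age_start, age_end + 1)
    hazard = gompertz_level * np.exp(gompertz_slope * (ages - age_start))
    return np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)


def generate_depression_schedule(
    bands: Sequence[PrevalenceBand] = DEFAULT_PREVALENCE_BANDS,
    multiplier: float = 1.74,
    age_start: int = 20,
    age_end: int = 70,
) -> np.ndarray:
    """Per-age 12-month depression probabilities for a primary-care cohort.

    Each age receives its band's general-population prevalence times the
    primary-care ``multiplier``; the product is clipped to 1 (with a
    warning) if the multiplier pushes it past a valid probability.
    """
    if multiplier <= 0:
        raise ValueError(f"multiplier must be positive, got {multiplier!r}")
    ordered = sorted(bands, key=lambda b: b.age_lo)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.age_lo <= prev.age_hi:
            raise ValueError(
                f"overlapping bands: ({prev.age_lo}-{prev.age_hi}) and "
                f"({nxt.age_lo}-{nxt.age_hi})"
            )
        if nxt.age_lo != prev.age_hi + 1:
            raise ValueError(
                f"gap between bands: ({prev.age_lo}-{prev.age_hi}) and "
                f"({nxt.age_lo}-{nxt.age_hi})"
            )
    if not ordered or ordered[0].age_lo > age_start or ordered[-1].age_hi < age_end:
        raise ValueError(
            f"bands must cover ages {age_start}-{age_end}"
        )
    out = np.empty(age_end - age_start + 1)
    for band in ordered:
        lo = max(band.age_lo, age_start)
        hi = min(band.age_hi, age_end)
        out[lo - age_start : hi - age_start + 1] = band.prevalence * multiplier
    if np.any(out > 1.0):
        warnings.warn(
            "depression probability exceeded 1 after applying the primary-care "
            "multiplier; clipping to 1",
            stacklevel=2,
        )
        out = np.clip(out, 0.0, 1.0)
    return out


def default_schedule(
    age_start: int = 20,
    age_end: int = 70,
    gompertz_level: float = DEFAULT_GOMPERTZ_LEVEL,
    gompertz_slope: float = DEFAULT_GOMPERTZ_SLOPE,
    bands: Sequence[PrevalenceBand] = DEFAULT_PREVALENCE_BANDS,
    multiplier: float = 1.74,
) -> AgeSchedule:
    """The calibrated synthetic schedule used throughout the test-bench."""
    ages = np.arange(age_start, age_end + 1)
    return AgeSchedule(
        pd.DataFrame(
            {
                "age": ages,
                "p_depression": generate_depression_schedule(
                    bands, multiplier, age_start, age_end
                ),
                "p_death": generate_mortality_schedule(
                    age_start, age_end, gompertz_level, gompertz_slope
                ),
            }
        )
    )


def read_schedule(path: str | Path) -> AgeSchedule:
    """Read an ``age,p_depression,p_death`` CSV; invariants are checked."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"schedule file not found: {path}")
    return AgeSchedule(pd.read_csv(path))


def write_schedule(schedule: AgeSchedule, path: str | Path) -> None:
    """Write a schedule as plain CSV with deterministic fixed-point formatting."""
    table = schedule.table.copy()
    table["p_depression"] = table["p_depression"].map(lambda v: f"{v:.10f}")
    table["p_death"] = table["p_death"].map(lambda v: f"{v:.10f}")
    table.to_csv(path, index=False)


def discounted_survival(
    schedule: AgeSchedule,
    discount_rate: float = 0.03,
    age_start: int = 20,
    age_end: int = 70,
) -> float:
    """Discounted survival-years over annual cycles at [age_start, age_end).

    Each cycle contributes ``survival-at-cycle-start / (1 + r)^t``; this is
    the quality-unadjusted annuity the mortality defaults are calibrated
    against (25-27 years at 3% over ages 20-70).
    """
    _, _, p_death = schedule.arrays(age_start, age_end)
    total = 0.0
    survival = 1.0
    for t, q in enumerate(p_death):
        total += survival / (1.0 + discount_rate) ** t
        survival *= 1.0 - q
    return total
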
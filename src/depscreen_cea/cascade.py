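"""Algebra of the one- and two-stage screening cascade.

Two-stage (series) screening administers the PHQ-9 only to PHQ-2
positives: overall sensitivity is the product of the stage sensitivities
and overall specificity is the complement of both stages falsely
flagging a well person.  The tests are treated as conditionally
independent given true depression status.  That assumption is built into
the multiplication; it is optimistic in practice because the PHQ-2 items
are a subset of the PHQ-9 items, so the two stages are positively
correlated and the realised joint specificity will be somewhat lower
than the series formula suggests.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import CostSet, TestCharacteristics

__all__ = [
    "ClassificationProbs",
    "combined_characteristics",
    "classification",
    "phq2_positive_rate",
    "screening_cost",
]

SCREENING_MODES = ("two_stage", "phq9_only")


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ClassificationProbs:
    """Population split into the four diagnostic classes for one screen."""

    p_true_positive: float
    p_false_negative: float
    p_false_positive: float
    p_true_negative: float

    def __post_init__(self) -> None:
        for name in (
            "p_true_positive",
            "p_false_negative",
            "p_false_positive",
            "p_true_negative",
        ):
            _check_unit(name, getattr(self, name))
        total = (
            self.p_true_positive
            + self.p_false_negative
            + self.p_false_positive
            + self.p_true_negative
        )
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"classification probabilities must sum to 1, got {total!r}")


def combined_characteristics(
    phq2: TestCharacteristics, phq9: TestCharacteristics, mode: str
) -> tuple[float, float]:
    """Joint (sensitivity, specificity) of the screening strategy.

    ``two_stage``: series positivity -- a person screens positive only if
    both stages are positive.  ``phq9_only``: the PHQ-9's own pair.
    """
    if mode == "two_stage":
        sensitivity = phq2.sensitivity * phq9.sensitivity
        specificity = 1.0 - (1.0 - phq2.specificity) * (1.0 - phq9.specificity)
        return sensitivity, specificity
    if mode == "phq9_only":
        return phq9.sensitivity, phq9.specificity
    raise ValueError(f"mode must be one of {SCREENING_MODES}, got {mode!r}")


def classification(
    prevalence: float, sensitivity: float, specificity: float
) -> ClassificationProbs:
    """Split a population of given prevalence into TP/FN/FP/TN fractions."""
    _check_unit("prevalence", prevalence)
    _check_unit("sensitivity", sensitivity)
    _check_unit("specificity", specificity)
    return ClassificationProbs(
        p_true_positive=prevalence * sensitivity,
        p_false_negative=prevalence * (1.0 - sensitivity),
        p_false_positive=(1.0 - prevalence) * (1.0 - specificity),
        p_true_negative=(1.0 - prevalence) * specificity,
    )


def phq2_positive_rate(prevalence: float, phq2: TestCharacteristics) -> float:
    """Probability of a positive PHQ-2 (true plus false positives)."""
    _check_unit("prevalence", prevalence)
    return prevalence * phq2.sensitivity + (1.0 - prevalence) * (1.0 - phq2.specificity)


def screening_cost(costs: CostSet, p_phq2_positive: float, mode: str) -> float:
    """Expected clinician cost (USD) of one screening administration.

    A nurse administers the process; a physician reviews the PHQ-2 score
    and, for PHQ-2 positives only, the PHQ-9.  In ``phq9_only`` mode the
    physician reviews the PHQ-9 for everyone and ``p_phq2_positive`` is
    ignored.
    """
    _check_unit("p_phq2_positive", p_phq2_positive)
    nurse = costs.wage_rn * costs.minutes_rn / 60.0
    if mode == "two_stage":
        return (
            nurse
            + costs.wage_gp * costs.minutes_gp_phq2 / 60.0
            + p_phq2_positive * costs.wage_gp * costs.minutes_gp_phq9 / 60.0
        )
    if mode == "phq9_only":
        return nurse + costs.wage_gp * costs.minutes_gp_phq9 / 60.0
    raise ValueError(f"mode must be one of {SCREENING_MODES}, got {mode!r}")
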
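"""Model inputs for the screening / collaborative-care decision model.

Every quantity the model consumes lives here: health-state utilities,
annual treatment and productivity costs, care-pathway probabilities,
PHQ-2/PHQ-9 operating characteristics, and the global model settings
(discount rate, age horizon, primary-care prevalence multiplier).

Parameters form a flat string registry so that the one-way sensitivity
machinery and the probabilistic sensitivity analysis can perturb any of
them generically; each registered parameter carries a triangular
(low, mode, high) uncertainty distribution.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

__all__ = [
    "ConfigError",
    "UnknownParameterError",
    "TriangularParam",
    "TestCharacteristics",
    "CarePathway",
    "UtilitySet",
    "CostSet",
    "ModelParameters",
    "load_config",
    "save_config",
    "with_override",
    "registered_parameters",
    "REFERENCE_SCREENING_COST",
]

#: Per-administration cost of the two-stage screen in the shipped inputs
#: (USD).  The engine computes screening cost bottom-up from wages and
#: minutes; the registered ``c_screening`` parameter rescales that
#: computation relative to this reference so the screening-cost
#: uncertainty band remains expressible.
REFERENCE_SCREENING_COST = 5.0

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration value violates the documented schema or an invariant."""


class UnknownParameterError(KeyError):
    """A parameter name is not in the registry."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ConfigError(f"{name} must be nonnegative, got {value!r}")


@dataclass(frozen=True)
class TriangularParam:
    """A triangular(low, mode, high) uncertainty distribution for one input."""

    low: float
    base: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ConfigError(
                f"triangular parameter requires low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )


@dataclass(frozen=True)
class TestCharacteristics:
    """Operating characteristics of one screening instrument at a cut-off.

    ``alternates`` maps alternative cut-off scores to their published
    (sensitivity, specificity) pairs, so that overriding the cut-off swaps
    in the matching pair.
    """

    cutoff: int
    sensitivity: float
    specificity: float
    alternates: Mapping[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_prob("sensitivity", self.sensitivity)
        _check_prob("specificity", self.specificity)
        for cut, (se, sp) in self.alternates.items():
            _check_prob(f"alternates[{cut}].sensitivity", se)
            _check_prob(f"alternates[{cut}].specificity", sp)

    def at_cutoff(self, cutoff: int) -> "TestCharacteristics":
        """Return a copy using the (sensitivity, specificity) pair for ``cutoff``."""
        if cutoff == self.cutoff:
            return self
        try:
            se, sp = self.alternates[cutoff]
        except KeyError:
            known = sorted({self.cutoff, *self.alternates})
            raise UnknownParameterError(
                f"no operating characteristics registered for cut-off {cutoff}; "
                f"known cut-offs: {known}"
            ) from None
        alternates = dict(self.alternates)
        alternates[self.cutoff] = (self.sensitivity, self.specificity)
        alternates.pop(cutoff, None)
        return TestCharacteristics(cutoff, se, sp, alternates)


@dataclass(frozen=True)
class CarePathway:
    """Probabilities along the detection -> treatment -> remission cascade."""

    p_treatable: float
    p_diagnosis_status_quo: float
    p_treatment_if_diagnosed: float
    p_adequate_cc: float
    p_adequate_uc: float

    def __post_init__(self) -> None:
        for name in (
            "p_treatable",
            "p_diagnosis_status_quo",
            "p_treatment_if_diagnosed",
            "p_adequate_cc",
            "p_adequate_uc",
        ):
            _check_prob(name, getattr(self, name))


@dataclass(frozen=True)
class UtilitySet:
    """Health-related quality-of-life weights for the annual health states.

    ``u_well`` is the weight for a non-depressed (or false-positive) year.
    The published inputs give no value for it; 1.0 is consistent with the
    QALY convention of one year of perfect health and with the assumption
    that healthy people gain no utility from treatment.
    """

    u_depressed: float
    u_remission: float
    u_well: float = 1.0

    def __post_init__(self) -> None:
        for name in ("u_depressed", "u_remission", "u_well"):
            _check_prob(name, getattr(self, name))
        if not (self.u_depressed <= self.u_remission <= self.u_well):
            raise ConfigError(
                "utilities must satisfy u_depressed <= u_remission <= u_well, got "
                f"({self.u_depressed}, {self.u_remission}, {self.u_well})"
            )


@dataclass(frozen=True)
class CostSet:
    """Annual costs (constant 2015 USD) and screening wage/time inputs.

    Lost productivity is stored as its absenteeism and presenteeism
    components; ``c_productivity_total`` is their sum.  Overriding the
    total rescales both components proportionally so the identity is
    preserved.
    """

    c_treatment_cc: float
    c_treatment_uc: float
    c_screening_two_stage: float
    c_absenteeism: float
    c_presenteeism: float
    wage_gp: float
    wage_rn: float
    minutes_gp_phq2: float
    minutes_gp_phq9: float
    minutes_rn: float

    def __post_init__(self) -> None:
        for name in (
            "c_treatment_cc",
            "c_treatment_uc",
            "c_screening_two_stage",
            "c_absenteeism",
            "c_presenteeism",
            "wage_gp",
            "wage_rn",
            "minutes_gp_phq2",
            "minutes_gp_phq9",
            "minutes_rn",
        ):
            _check_nonneg(name, getattr(self, name))

    @property
    def c_productivity_total(self) -> float:
        return self.c_absenteeism + self.c_presenteeism

    def with_productivity_total(self, total: float) -> "CostSet":
        _check_nonneg("c_productivity_total", total)
        current = self.c_productivity_total
        if current > 0:
            factor = total / current
            return replace(
                self,
                c_absenteeism=self.c_absenteeism * factor,
                c_presenteeism=self.c_presenteeism * factor,
            )
        return replace(self, c_absenteeism=total, c_presenteeism=0.0)


#: Policies for how remissions achieved in an intervention arm feed back
#: into the next cycle's probability of depression.
FEEDBACK_POLICIES = ("incremental_remissions", "proportional", "none")


@dataclass(frozen=True)
class ModelParameters:
    """The full, validated input set for one model run."""

    phq2: TestCharacteristics
    phq9: TestCharacteristics
    pathway: CarePathway
    utilities: UtilitySet
    costs: CostSet
    discount_rate: float = 0.03
    age_start: int = 20
    age_end: int = 70
    primary_care_multiplier: float = 1.74
    wtp_reference: float = 40_000.0
    productivity_age_cap: Optional[int] = None
    p_depression_scale: float = 1.0
    fn_fallback: bool = True
    screen_positive_treatment_gate: bool = True
    feedback_policy: str = "incremental_remissions"
    triangulars: Mapping[str, TriangularParam] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_start >= self.age_end:
            raise ConfigError(
                f"age_start ({self.age_start}) must be below age_end ({self.age_end})"
            )
        _check_nonneg("discount_rate", self.discount_rate)
        if self.primary_care_multiplier <= 0:
            raise ConfigError(
                f"primary_care_multiplier must be positive, got {self.primary_care_multiplier!r}"
            )
        _check_nonneg("wtp_reference", self.wtp_reference)
        _check_nonneg("p_depression_scale", self.p_depression_scale)
        if self.feedback_policy not in FEEDBACK_POLICIES:
            raise ConfigError(
                f"feedback_policy must be one of {FEEDBACK_POLICIES}, "
                f"got {self.feedback_policy!r}"
            )

    @property
    def horizon_years(self) -> int:
        return self.age_end - self.age_start


# ---------------------------------------------------------------------------
# Parameter registry

def _set_pathway(params: ModelParameters, name: str, value: float) -> ModelParameters:
    return replace(params, pathway=replace(params.pathway, **{name: value}))


def _set_utility(params: ModelParameters, name: str, value: float) -> ModelParameters:
    return replace(params, utilities=replace(params.utilities, **{name: value}))


def _set_cost(params: ModelParameters, name: str, value: float) -> ModelParameters:
    return replace(params, costs=replace(params.costs, **{name: value}))


def _set_test(params: ModelParameters, instrument: str, attr: str, value: float) -> ModelParameters:
    test = getattr(params, instrument)
    return replace(params, **{instrument: replace(test, **{attr: value})})


_SCALAR_SETTERS = {
    "u_depressed": lambda p, v: _set_utility(p, "u_depressed", v),
    "u_remission": lambda p, v: _set_utility(p, "u_remission", v),
    "c_treatment_cc": lambda p, v: _set_cost(p, "c_treatment_cc", v),
    "c_treatment_uc": lambda p, v: _set_cost(p, "c_treatment_uc", v),
    "c_screening": lambda p, v: _set_cost(p, "c_screening_two_stage", v),
    "c_productivity_total": lambda p, v: replace(
        p, costs=p.costs.with_productivity_total(v)
    ),
    "p_treatable": lambda p, v: _set_pathway(p, "p_treatable", v),
    "p_diagnosis_status_quo": lambda p, v: _set_pathway(p, "p_diagnosis_status_quo", v),
    "p_treatment_if_diagnosed": lambda p, v: _set_pathway(p, "p_treatment_if_diagnosed", v),
    "p_adequate_cc": lambda p, v: _set_pathway(p, "p_adequate_cc", v),
    "p_adequate_uc": lambda p, v: _set_pathway(p, "p_adequate_uc", v),
    "se_phq2": lambda p, v: _set_test(p, "phq2", "sensitivity", v),
    "sp_phq2": lambda p, v: _set_test(p, "phq2", "specificity", v),
    "se_phq9": lambda p, v: _set_test(p, "phq9", "sensitivity", v),
    "sp_phq9": lambda p, v: _set_test(p, "phq9", "specificity", v),
    "p_depression_scale": lambda p, v: replace(p, p_depression_scale=v),
}

_SCALAR_GETTERS = {
    "u_depressed": lambda p: p.utilities.u_depressed,
    "u_remission": lambda p: p.utilities.u_remission,
    "c_treatment_cc": lambda p: p.costs.c_treatment_cc,
    "c_treatment_uc": lambda p: p.costs.c_treatment_uc,
    "c_screening": lambda p: p.costs.c_screening_two_stage,
    "c_productivity_total": lambda p: p.costs.c_productivity_total,
    "p_treatable": lambda p: p.pathway.p_treatable,
    "p_diagnosis_status_quo": lambda p: p.pathway.p_diagnosis_status_quo,
    "p_treatment_if_diagnosed": lambda p: p.pathway.p_treatment_if_diagnosed,
    "p_adequate_cc": lambda p: p.pathway.p_adequate_cc,
    "p_adequate_uc": lambda p: p.pathway.p_adequate_uc,
    "se_phq2": lambda p: p.phq2.sensitivity,
    "sp_phq2": lambda p: p.phq2.specificity,
    "se_phq9": lambda p: p.phq9.sensitivity,
    "sp_phq9": lambda p: p.phq9.specificity,
    "p_depression_scale": lambda p: p.p_depression_scale,
}

#: Cut-off overrides swap in the matching (sensitivity, specificity) pair.
_CUTOFF_PARAMETERS = {"phq2_cutoff": "phq2", "phq9_cutoff": "phq9"}


def registered_parameters(params: Optional[ModelParameters] = None) -> tuple[str, ...]:
    """Names accepted by :func:`with_override` (scalar registry plus cut-offs)."""
    names = list(_SCALAR_SETTERS) + list(_CUTOFF_PARAMETERS) + ["productivity_age_cap"]
    return tuple(names)


def get_parameter(params: ModelParameters, name: str) -> float:
    """Current value of a registered scalar parameter or cut-off."""
    if name in _SCALAR_GETTERS:
        return _SCALAR_GETTERS[name](params)
    if name in _CUTOFF_PARAMETERS:
        return getattr(params, _CUTOFF_PARAMETERS[name]).cutoff
    if name == "productivity_age_cap":
        return params.productivity_age_cap
    raise UnknownParameterError(
        f"unknown parameter {name!r}; registered: {sorted(registered_parameters())}"
    )


def with_override(params: ModelParameters, name: str, value) -> ModelParameters:
    """Return a new parameter set differing only in the named parameter.

    Overriding a cut-off (``phq2_cutoff`` / ``phq9_cutoff``) swaps in the
    corresponding (sensitivity, specificity) pair from the instrument's
    registered alternates.
    """
    if name in _SCALAR_SETTERS:
        return _SCALAR_SETTERS[name](params, float(value))
    if name in _CUTOFF_PARAMETERS:
        instrument = _CUTOFF_PARAMETERS[name]
        test = getattr(params, instrument).at_cutoff(int(value))
        return replace(params, **{instrument: test})
    if name == "productivity_age_cap":
        cap = None if value is None else int(value)
        return replace(params, productivity_age_cap=cap)
    raise UnknownParameterError(
        f"unknown parameter {name!r}; registered: {sorted(registered_parameters())}"
    )


# ---------------------------------------------------------------------------
# Configuration files

def _default_config() -> dict:
    text = resources.files("depscreen_cea").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _require_number(section: Mapping, key: str, context: str) -> float:
    try:
        value = section[key]
    except (KeyError, TypeError):
        raise ConfigError(f"missing required field {context}.{key}") from None
    if not isinstance(value, numbers.Real) or isinstance(value, bool):
        raise ConfigError(f"{context}.{key} must be a number, got {value!r}")
    return float(value)


def _test_from_config(section: Mapping, context: str) -> TestCharacteristics:
    cutoff = int(_require_number(section, "cutoff", context))
    se = _require_number(section, "sensitivity", context)
    sp = _require_number(section, "specificity", context)
    alternates = {}
    for cut, pair in (section.get("alternates") or {}).items():
        if not isinstance(pair, (list, tuple)) or len(pair) != 2:
            raise ConfigError(
                f"{context}.alternates[{cut}] must be a [sensitivity, specificity] pair"
            )
        alternates[int(cut)] = (float(pair[0]), float(pair[1]))
    try:
        return TestCharacteristics(cutoff, se, sp, alternates)
    except ConfigError as exc:
        raise ConfigError(f"{context}: {exc}") from None


def _params_from_config(config: Mapping) -> ModelParameters:
    if config.get("schema") != CONFIG_SCHEMA_VERSION:
        raise ConfigError(
            f"config schema must be {CONFIG_SCHEMA_VERSION}, got {config.get('schema')!r}"
        )
    model = config.get("model") or {}
    util = config.get("utilities") or {}
    cost = config.get("costs") or {}
    prob = config.get("probabilities") or {}

    utilities = UtilitySet(
        u_depressed=_require_number(util, "depressed", "utilities"),
        u_remission=_require_number(util, "remission", "utilities"),
        u_well=_require_number(util, "well", "utilities"),
    )
    costs = CostSet(
        c_treatment_cc=_require_number(cost, "treatment_cc", "costs"),
        c_treatment_uc=_require_number(cost, "treatment_uc", "costs"),
        c_screening_two_stage=_require_number(cost, "screening_two_stage", "costs"),
        c_absenteeism=_require_number(cost, "absenteeism", "costs"),
        c_presenteeism=_require_number(cost, "presenteeism", "costs"),
        wage_gp=_require_number(cost, "wage_gp", "costs"),
        wage_rn=_require_number(cost, "wage_rn", "costs"),
        minutes_gp_phq2=_require_number(cost, "minutes_gp_phq2", "costs"),
        minutes_gp_phq9=_require_number(cost, "minutes_gp_phq9", "costs"),
        minutes_rn=_require_number(cost, "minutes_rn", "costs"),
    )
    pathway = CarePathway(
        p_treatable=_require_number(prob, "treatable", "probabilities"),
        p_diagnosis_status_quo=_require_number(prob, "diagnosis_status_quo", "probabilities"),
        p_treatment_if_diagnosed=_require_number(prob, "treatment_if_diagnosed", "probabilities"),
        p_adequate_cc=_require_number(prob, "adequate_cc", "probabilities"),
        p_adequate_uc=_require_number(prob, "adequate_uc", "probabilities"),
    )
    triangulars = {}
    for name, triple in (config.get("triangulars") or {}).items():
        if not isinstance(triple, (list, tuple)) or len(triple) != 3:
            raise ConfigError(f"triangulars.{name} must be a [low, base, high] triple")
        low, base, high = (float(v) for v in triple)
        try:
            triangulars[str(name)] = TriangularParam(low, base, high)
        except ConfigError as exc:
            raise ConfigError(f"triangulars.{name}: {exc}") from None

    cap = model.get("productivity_age_cap")
    return ModelParameters(
        phq2=_test_from_config(config.get("phq2") or {}, "phq2"),
        phq9=_test_from_config(config.get("phq9") or {}, "phq9"),
        pathway=pathway,
        utilities=utilities,
        costs=costs,
        discount_rate=_require_number(model, "discount_rate", "model"),
        age_start=int(_require_number(model, "age_start", "model")),
        age_end=int(_require_number(model, "age_end", "model")),
        primary_care_multiplier=_require_number(model, "primary_care_multiplier", "model"),
        wtp_reference=_require_number(model, "wtp_reference", "model"),
        productivity_age_cap=None if cap is None else int(cap),
        p_depression_scale=_require_number(model, "p_depression_scale", "model"),
        fn_fallback=bool(model.get("fn_fallback", True)),
        screen_positive_treatment_gate=bool(model.get("screen_positive_treatment_gate", True)),
        feedback_policy=str(model.get("feedback_policy", "incremental_remissions")),
        triangulars=triangulars,
    )


def load_config(path: Optional[str | Path] = None) -> ModelParameters:
    """Load and validate a model configuration.

    ``path=None`` loads the shipped defaults.  A user file only needs the
    fields it changes; everything omitted falls back to the defaults.
    """
    config = _default_config()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        user = yaml.safe_load(path.read_text())
        if user is None:
            user = {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        user = dict(user)
        user.setdefault("schema", CONFIG_SCHEMA_VERSION)
        config = _merge(config, user)
    return _params_from_config(config)


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write a complete configuration that round-trips through :func:`load_config`."""
    config = {
        "schema": CONFIG_SCHEMA_VERSION,
        "model": {
            "discount_rate": params.discount_rate,
            "age_start": params.age_start,
            "age_end": params.age_end,
            "primary_care_multiplier": params.primary_care_multiplier,
            "wtp_reference": params.wtp_reference,
            "productivity_age_cap": params.productivity_age_cap,
            "p_depression_scale": params.p_depression_scale,
            "fn_fallback": params.fn_fallback,
            "screen_positive_treatment_gate": params.screen_positive_treatment_gate,
            "feedback_policy": params.feedback_policy,
        },
        "utilities": {
            "depressed": params.utilities.u_depressed,
            "remission": params.utilities.u_remission,
            "well": params.utilities.u_well,
        },
        "costs": {
            "treatment_cc": params.costs.c_treatment_cc,
            "treatment_uc": params.costs.c_treatment_uc,
            "screening_two_stage": params.costs.c_screening_two_stage,
            "absenteeism": params.costs.c_absenteeism,
            "presenteeism": params.costs.c_presenteeism,
            "wage_gp": params.costs.wage_gp,
            "wage_rn": params.costs.wage_rn,
            "minutes_gp_phq2": params.costs.minutes_gp_phq2,
            "minutes_gp_phq9": params.costs.minutes_gp_phq9,
            "minutes_rn": params.costs.minutes_rn,
        },
        "probabilities": {
            "treatable": params.pathway.p_treatable,
            "diagnosis_status_quo": params.pathway.p_diagnosis_status_quo,
            "treatment_if_diagnosed": params.pathway.p_treatment_if_diagnosed,
            "adequate_cc": params.pathway.p_adequate_cc,
            "adequate_uc": params.pathway.p_adequate_uc,
        },
        "phq2": {
            "cutoff": params.phq2.cutoff,
            "sensitivity": params.phq2.sensitivity,
            "specificity": params.phq2.specificity,
            "alternates": {
                cut: list(pair) for cut, pair in sorted(params.phq2.alternates.items())
            },
        },
        "phq9": {
            "cutoff": params.phq9.cutoff,
            "sensitivity": params.phq9.sensitivity,
            "specificity": params.phq9.specificity,
            "alternates": {
                cut: list(pair) for cut, pair in sorted(params.phq9.alternates.items())
            },
        },
        "triangulars": {
            name: [tri.low, tri.base, tri.high]
            for name, tri in sorted(params.triangulars.items())
        },
    }
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
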
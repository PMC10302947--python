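"""Model parameters: schema, config loading/validation, uncertainty distributions.

Every quantitative model input — annual transition probabilities between
blood-pressure states, state-specific complication hazards, costs, utility
weights, compliance rates and the discount rate — is carried as a
:class:`Param`: a base-case value plus an uncertainty distribution (Beta for
probabilities, Triangular for costs and the discount rate, or a degenerate
point mass).  The base-case run reads ``Param.value``; the probabilistic
sensitivity analysis redraws every distributed parameter with
:func:`sample_parameter_set`.

Configuration is a single hierarchical YAML file with blocks ``transition``,
``hazards``, ``costs``, ``utilities``, ``compliance``, ``efficacy``,
``economics``, ``care_model`` and ``risk_model`` (see the bundled
``data/default_config.yaml``, and ``data/config_schema.json`` for a
machine-readable description).  All monetary values are USD, all rates are
per year.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "STATES",
    "COMPLICATIONS",
    "ConfigError",
    "Distribution",
    "Param",
    "TransitionRates",
    "HazardBlock",
    "ComplicationHazards",
    "CostSchedule",
    "UtilitySchedule",
    "Compliance",
    "Efficacy",
    "CareModel",
    "CovariateSpec",
    "RiskModel",
    "ParameterSet",
    "distribution_mean",
    "load_parameters",
    "load_default_parameters",
    "default_config_path",
    "dump_parameters",
    "sample_parameter_set",
    "validate_parameter_set",
    "iter_params",
    "SECTION24_HAZARDS",
]

#: Canonical ordering of the four blood-pressure states.
STATES = ("normal", "pre", "stage1", "stage2")

#: The three modelled end-organ complications.
COMPLICATIONS = ("ami", "stroke", "esrd")


class ConfigError(ValueError):
    """A configuration file failed schema or invariant validation."""


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Distribution:
    """Uncertainty distribution of a single parameter.

    ``kind`` is one of ``"beta"``, ``"triangular"`` or ``"point"`` and
    ``params`` holds ``(alpha, beta)``, ``(low, mode, high)`` or ``(value,)``
    respectively.
    """

    kind: str
    params: tuple

    # -- constructors -------------------------------------------------------
    @classmethod
    def beta(cls, alpha: float, beta: float) -> "Distribution":
        if not (alpha > 0 and beta > 0):
            raise ConfigError(f"beta distribution requires alpha,beta > 0, got ({alpha}, {beta})")
        return cls("beta", (float(alpha), float(beta)))

    @classmethod
    def triangular(cls, low: float, mode: float, high: float) -> "Distribution":
        if not (low <= mode <= high):
            raise ConfigError(
                f"triangular distribution requires low <= mode <= high, got ({low}, {mode}, {high})"
            )
        return cls("triangular", (float(low), float(mode), float(high)))

    @classmethod
    def point(cls, value: float) -> "Distribution":
        return cls("point", (float(value),))

    # -- moments & sampling -------------------------------------------------
    def mean(self) -> float:
        if self.kind == "beta":
            a, b = self.params
            return a / (a + b)
        if self.kind == "triangular":
            low, mode, high = self.params
            return (low + mode + high) / 3.0
        return self.params[0]

    def base_value(self) -> float:
        """Default base-case value when the config gives no explicit one.

        Beta parameters default to their mean, triangular ones to their mode
        (the "most likely" value), point masses to themselves.
        """
        if self.kind == "triangular":
            return self.params[1]
        return self.mean()

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "beta":
            a, b = self.params
            return float(rng.beta(a, b))
        if self.kind == "triangular":
            low, mode, high = self.params
            if low == high:  # degenerate; numpy rejects left==right
                return float(mode)
            return float(rng.triangular(low, mode, high))
        return self.params[0]


def distribution_mean(d: Distribution) -> float:
    """Closed-form mean of a parameter distribution.

    Beta(a, b) -> a/(a+b); Triangular(l, m, h) -> (l+m+h)/3; point -> value.
    """
    return d.mean()


@dataclass(frozen=True)
class Param:
    """One model input: a base-case value plus its uncertainty distribution.

    ``assumption`` flags values that are modelling assumptions rather than
    published estimates; ``source`` is a free-text provenance tag used by the
    CLI audit log.
    """

    value: float
    dist: Distribution = None  # type: ignore[assignment]
    assumption: bool = False
    source: str = ""

    def __post_init__(self):
        if self.dist is None:
            object.__setattr__(self, "dist", Distribution.point(self.value))

    def sampled(self, rng: np.random.Generator) -> "Param":
        """A copy with ``value`` replaced by one draw from ``dist``."""
        return dataclasses.replace(self, value=self.dist.sample(rng))


# ---------------------------------------------------------------------------
# Structured parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class TransitionRates:
    """Annual transition probabilities of the four-state natural history.

    Progression normal→pre→stage I→stage II plus the single regression
    pre→normal; all other moves are structurally impossible.
    """

    normal_to_pre: Param
    pre_to_stage1: Param
    stage1_to_stage2: Param
    pre_to_normal: Param


@dataclass
class HazardBlock:
    """Annual hazard of one complication per blood-pressure state, plus case fatality."""

    normal: Param
    pre: Param
    stage1: Param
    stage2: Param
    mortality_immediate: Param
    mortality_yearly: Param

    def state_probs(self) -> np.ndarray:
        return np.array([self.normal.value, self.pre.value, self.stage1.value, self.stage2.value])


@dataclass
class ComplicationHazards:
    ami: HazardBlock
    stroke: HazardBlock
    esrd: HazardBlock

    def __getitem__(self, name: str) -> HazardBlock:
        return getattr(self, name)


#: Keys of the cost schedule (all USD; *_annual and lifestyle/checkup items per year).
COST_KEYS = (
    "mi_admission",
    "mi_visit",
    "stroke_admission",
    "stroke_visit",
    "esrd_annual",
    "htn_admission",
    "htn_visit",
    "lifestyle_low",
    "lifestyle_mid",
    "lifestyle_full",
    "checkup_regular",
    "checkup_advanced",
    "screening",
    "terminal_care",
    "drug",
)


@dataclass
class CostSchedule:
    mi_admission: Param
    mi_visit: Param
    stroke_admission: Param
    stroke_visit: Param
    esrd_annual: Param
    htn_admission: Param
    htn_visit: Param
    lifestyle_low: Param
    lifestyle_mid: Param
    lifestyle_full: Param
    checkup_regular: Param
    checkup_advanced: Param
    screening: Param
    terminal_care: Param
    drug: Param

    def __getitem__(self, key: str) -> Param:
        if key not in COST_KEYS:
            raise KeyError(f"unknown cost key {key!r}")
        return getattr(self, key)


@dataclass
class UtilitySchedule:
    """QALY weights: one per disease state, one multiplier per complication.

    The weight of a lived year is state weight times the product (or minimum,
    per ``combination_rule``) of the multipliers of all complications carried.
    Death carries weight 0.
    """

    state: dict  # state name -> weight in [0, 1]
    complication: dict  # complication name -> multiplier in [0, 1]
    combination_rule: str = "product"  # or "minimum"


@dataclass
class Compliance:
    lifestyle: Param
    screening: Param
    medication: Param


@dataclass
class Efficacy:
    """Achievable blood-pressure reduction per state (mm Hg).

    Systolic reductions drive the hazard-ratio mapping; diastolic figures are
    carried for completeness but unused.  Awareness/lifestyle activities do
    not lower blood pressure in stage II (clinically overt disease); only
    pharmacological treatment does.
    """

    sbp_reduction: dict  # state -> mm Hg
    dbp_reduction: dict = field(default_factory=dict)


@dataclass
class CareModel:
    """Annual health-care utilisation assumptions attached to states/complications."""

    mi_visits_per_year: float = 4.0
    stroke_visits_per_year: float = 4.0
    htn_visits_per_year: dict = field(default_factory=lambda: {"stage1": 2.0, "stage2": 4.0})
    htn_admissions_per_year: dict = field(default_factory=lambda: {"stage1": 0.01, "stage2": 0.05})


@dataclass
class CovariateSpec:
    """One synthetic risk-factor: sampling distribution and its true score weight."""

    name: str
    distribution: str  # "normal" or "bernoulli"
    weight: float
    mu: float = 0.0
    sigma: float = 1.0
    p: float = 0.5


@dataclass
class RiskModel:
    """Log-linear state-specific risk score: score = intercept + w·x.

    exp(score) multiplies progression rates (proportional-hazards
    convention); the regression rate pre→normal is unaffected unless
    ``modify_regression`` is set.
    """

    intercept: float = 0.0
    covariates: list = field(default_factory=list)  # list[CovariateSpec]
    cutoffs: tuple | None = None  # None -> tertiles of the simulated scores
    modify_regression: bool = False


@dataclass
class ParameterSet:
    """Everything a model run needs, with per-parameter uncertainty."""

    transition: TransitionRates
    hazards: ComplicationHazards
    costs: CostSchedule
    utilities: UtilitySchedule
    compliance: Compliance
    efficacy: Efficacy
    discount_rate: Param
    horizon_years: int
    initial_state_distribution: np.ndarray  # length 4, sums to 1
    care: CareModel = field(default_factory=CareModel)
    risk: RiskModel = field(default_factory=RiskModel)
    #: annual per-person intervention cost by disease state; attached by
    #: strategy application, zero in the raw natural-history parameter set
    intervention_cost_per_state: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Loading & validation
# ---------------------------------------------------------------------------


def _parse_dist(node, path: str) -> Distribution:
    if not isinstance(node, Mapping) or len(node) != 1:
        raise ConfigError(f"{path}: distribution must be a one-key mapping, got {node!r}")
    (kind, args), = node.items()
    if kind == "beta":
        if not (isinstance(args, Sequence) and len(args) == 2):
            raise ConfigError(f"{path}: beta takes [alpha, beta], got {args!r}")
        return Distribution.beta(*args)
    if kind == "triangular":
        if not (isinstance(args, Sequence) and len(args) == 3):
            raise ConfigError(f"{path}: triangular takes [low, mode, high], got {args!r}")
        return Distribution.triangular(*args)
    if kind == "point":
        return Distribution.point(args)
    raise ConfigError(f"{path}: unknown distribution kind {kind!r}")


def _parse_param(node, path: str, lo=None, hi=None) -> Param:
    """Parse a scalar or ``{value, dist, assumption, source}`` mapping."""
    if isinstance(node, (int, float)) and not isinstance(node, bool):
        p = Param(float(node))
    elif isinstance(node, Mapping):
        unknown = set(node) - {"value", "dist", "assumption", "source"}
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        dist = _parse_dist(node["dist"], path) if "dist" in node else None
        if "value" in node:
            value = float(node["value"])
        elif dist is not None:
            value = dist.base_value()
        else:
            raise ConfigError(f"{path}: needs 'value' or 'dist'")
        p = Param(value, dist, bool(node.get("assumption", False)), str(node.get("source", "")))
    else:
        raise ConfigError(f"{path}: expected number or mapping, got {node!r}")
    if lo is not None and p.value < lo:
        raise ConfigError(f"{path}: value {p.value} below lower bound {lo}")
    if hi is not None and p.value > hi:
        raise ConfigError(f"{path}: value {p.value} above upper bound {hi}")
    return p


def _require(block: Mapping, key: str, path: str):
    if not isinstance(block, Mapping) or key not in block:
        raise ConfigError(f"missing required key '{path}.{key}'" if path else f"missing required block '{key}'")
    return block[key]


def _load_hazard_block(node, path: str) -> HazardBlock:
    kwargs = {}
    for key in ("normal", "pre", "stage1", "stage2", "mortality_immediate", "mortality_yearly"):
        kwargs[key] = _parse_param(_require(node, key, path), f"{path}.{key}", lo=0.0, hi=1.0)
    return HazardBlock(**kwargs)


def load_parameters(path, preset: str = "table1") -> ParameterSet:
    """Load and validate a model configuration file.

    Parameters
    ----------
    path : str or Path
        YAML configuration file.
    preset : {"table1", "section24"}
        Which set of published base-case complication hazards to use where
        the two printed sources disagree.  ``table1`` (default) keeps the
        tabulated values; ``section24`` substitutes the narrative annual
        rates (MI 0.0032/0.0068/0.0095, stroke 0.0008/0.0018/0.0072, renal
        failure 0.002/0.0321/0.0462 for pre/stage I/stage II).  Uncertainty
        distributions are identical in both presets.

    Raises
    ------
    ConfigError
        On a missing key or an invariant violation, naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    ps = _from_dict(raw)
    if preset != "table1":
        _apply_preset(ps, preset)
    validate_parameter_set(ps)
    return ps


def _from_dict(raw: Mapping) -> ParameterSet:
    missing = [b for b in ("transition", "hazards", "costs", "utilities",
                           "compliance", "efficacy", "economics") if b not in raw]
    if missing:
        raise ConfigError(f"missing required block(s): {', '.join(missing)}")

    tr_node = raw["transition"]
    transition = TransitionRates(
        normal_to_pre=_parse_param(_require(tr_node, "normal_to_pre", "transition"),
                                   "transition.normal_to_pre", 0.0, 1.0),
        pre_to_stage1=_parse_param(_require(tr_node, "pre_to_stage1", "transition"),
                                   "transition.pre_to_stage1", 0.0, 1.0),
        stage1_to_stage2=_parse_param(_require(tr_node, "stage1_to_stage2", "transition"),
                                      "transition.stage1_to_stage2", 0.0, 1.0),
        pre_to_normal=_parse_param(_require(tr_node, "pre_to_normal", "transition"),
                                   "transition.pre_to_normal", 0.0, 1.0),
    )

    hz_node = raw["hazards"]
    hazards = ComplicationHazards(
        ami=_load_hazard_block(_require(hz_node, "ami", "hazards"), "hazards.ami"),
        stroke=_load_hazard_block(_require(hz_node, "stroke", "hazards"), "hazards.stroke"),
        esrd=_load_hazard_block(_require(hz_node, "esrd", "hazards"), "hazards.esrd"),
    )

    cost_node = raw["costs"]
    costs = CostSchedule(**{
        k: _parse_param(_require(cost_node, k, "costs"), f"costs.{k}", lo=0.0) for k in COST_KEYS
    })

    ut_node = raw["utilities"]
    state_w = {s: float(_require(_require(ut_node, "state", "utilities"), s, "utilities.state"))
               for s in STATES}
    comp_w = {c: float(_require(_require(ut_node, "complication", "utilities"), c,
                                "utilities.complication"))
              for c in COMPLICATIONS}
    utilities = UtilitySchedule(state=state_w, complication=comp_w,
                                combination_rule=str(ut_node.get("combination_rule", "product")))

    cp_node = raw["compliance"]
    compliance = Compliance(
        lifestyle=_parse_param(_require(cp_node, "lifestyle", "compliance"),
                               "compliance.lifestyle", 0.0, 1.0),
        screening=_parse_param(_require(cp_node, "screening", "compliance"),
                               "compliance.screening", 0.0, 1.0),
        medication=_parse_param(_require(cp_node, "medication", "compliance"),
                                "compliance.medication", 0.0, 1.0),
    )

    ef_node = raw["efficacy"]
    sbp = {s: float(v) for s, v in _require(ef_node, "sbp_reduction", "efficacy").items()}
    for s in STATES:
        if s not in sbp:
            raise ConfigError(f"missing required key 'efficacy.sbp_reduction.{s}'")
        if sbp[s] < 0:
            raise ConfigError(f"efficacy.sbp_reduction.{s}: reductions must be >= 0")
    dbp = {s: (None if v is None else float(v))
           for s, v in ef_node.get("dbp_reduction", {}).items()}
    efficacy = Efficacy(sbp_reduction=sbp, dbp_reduction=dbp)

    ec_node = raw["economics"]
    discount = _parse_param(_require(ec_node, "discount_rate", "economics"),
                            "economics.discount_rate", lo=0.0)
    horizon = int(_require(ec_node, "horizon_years", "economics"))
    init_node = _require(ec_node, "initial_state_distribution", "economics")
    init = np.array([float(_require(init_node, s, "economics.initial_state_distribution"))
                     for s in STATES])

    care_node = raw.get("care_model", {})
    care = CareModel(
        mi_visits_per_year=float(care_node.get("mi_visits_per_year", 4.0)),
        stroke_visits_per_year=float(care_node.get("stroke_visits_per_year", 4.0)),
        htn_visits_per_year={k: float(v) for k, v in
                             care_node.get("htn_visits_per_year",
                                           {"stage1": 2.0, "stage2": 4.0}).items()},
        htn_admissions_per_year={k: float(v) for k, v in
                                 care_node.get("htn_admissions_per_year",
                                               {"stage1": 0.01, "stage2": 0.05}).items()},
    )

    risk_node = raw.get("risk_model", {})
    covs = []
    for name, spec in risk_node.get("covariates", {}).items():
        kind = str(_require(spec, "distribution", f"risk_model.covariates.{name}"))
        if kind not in ("normal", "bernoulli"):
            raise ConfigError(f"risk_model.covariates.{name}: unknown distribution {kind!r}")
        covs.append(CovariateSpec(
            name=name, distribution=kind,
            weight=float(_require(spec, "weight", f"risk_model.covariates.{name}")),
            mu=float(spec.get("mu", 0.0)), sigma=float(spec.get("sigma", 1.0)),
            p=float(spec.get("p", 0.5)),
        ))
    cutoffs = risk_node.get("cutoffs")
    risk = RiskModel(
        intercept=float(risk_node.get("intercept", 0.0)),
        covariates=covs,
        cutoffs=None if cutoffs is None else tuple(float(c) for c in cutoffs),
        modify_regression=bool(risk_node.get("modify_regression", False)),
    )

    return ParameterSet(
        transition=transition, hazards=hazards, costs=costs, utilities=utilities,
        compliance=compliance, efficacy=efficacy, discount_rate=discount,
        horizon_years=horizon, initial_state_distribution=init, care=care, risk=risk,
    )


#: Narrative annual complication rates for pre / stage I / stage II, where the
#: running text and the parameter table disagree; applied by the "section24"
#: preset.  The normal-state hazards keep their tabulated values.
SECTION24_HAZARDS = {
    "ami": {"pre": 0.0032, "stage1": 0.0068, "stage2": 0.0095},
    "stroke": {"pre": 0.0008, "stage1": 0.0018, "stage2": 0.0072},
    "esrd": {"pre": 0.002, "stage1": 0.0321, "stage2": 0.0462},
}


def _apply_preset(ps: ParameterSet, preset: str) -> None:
    if preset != "section24":
        raise ConfigError(f"unknown preset {preset!r}; expected 'table1' or 'section24'")
    for comp, states in SECTION24_HAZARDS.items():
        block = ps.hazards[comp]
        for state, value in states.items():
            setattr(block, state, dataclasses.replace(getattr(block, state), value=value))


def validate_parameter_set(ps: ParameterSet, base_case: bool = True) -> None:
    """Check every structural invariant; raise :class:`ConfigError` on failure.

    ``base_case=False`` relaxes checks that hold only for published base-case
    values (hazard monotonicity across states), for use on sampled sets.
    """
    errors = []

    def prob(name, v):
        if not (0.0 <= v <= 1.0):
            errors.append(f"{name}: probability {v} outside [0, 1]")

    tr = ps.transition
    for name in ("normal_to_pre", "pre_to_stage1", "stage1_to_stage2", "pre_to_normal"):
        prob(f"transition.{name}", getattr(tr, name).value)
    if tr.pre_to_stage1.value + tr.pre_to_normal.value > 1.0 + 1e-12:
        errors.append(
            "transition: pre_to_stage1 + pre_to_normal = "
            f"{tr.pre_to_stage1.value + tr.pre_to_normal.value:.6g} exceeds 1"
        )

    for comp in COMPLICATIONS:
        block = ps.hazards[comp]
        for key in ("normal", "pre", "stage1", "stage2", "mortality_immediate", "mortality_yearly"):
            prob(f"hazards.{comp}.{key}", getattr(block, key).value)
        if base_case:
            probs = block.state_probs()
            if np.any(np.diff(probs) < -1e-12):
                errors.append(
                    f"hazards.{comp}: base-case hazards must be non-decreasing "
                    f"normal→pre→stage1→stage2, got {probs.tolist()}"
                )

    for key in COST_KEYS:
        if ps.costs[key].value < 0:
            errors.append(f"costs.{key}: negative cost {ps.costs[key].value}")

    for s, w in ps.utilities.state.items():
        if not (0.0 <= w <= 1.0):
            errors.append(f"utilities.state.{s}: weight {w} outside [0, 1]")
    for c, w in ps.utilities.complication.items():
        if not (0.0 <= w <= 1.0):
            errors.append(f"utilities.complication.{c}: weight {w} outside [0, 1]")
    if ps.utilities.state and max(ps.utilities.state, key=ps.utilities.state.get) != "normal":
        errors.append("utilities.state: the normal state must carry the highest weight")
    if ps.utilities.combination_rule not in ("product", "minimum"):
        errors.append(f"utilities.combination_rule: unknown rule {ps.utilities.combination_rule!r}")

    for name in ("lifestyle", "screening", "medication"):
        prob(f"compliance.{name}", getattr(ps.compliance, name).value)

    if not (0.0 <= ps.discount_rate.value <= 0.05):
        errors.append(f"economics.discount_rate: {ps.discount_rate.value} outside [0, 0.05]")
    if ps.horizon_years < 1:
        errors.append(f"economics.horizon_years: {ps.horizon_years} < 1")
    total = float(ps.initial_state_distribution.sum())
    if abs(total - 1.0) > 1e-9:
        errors.append(f"economics.initial_state_distribution: sums to {total}, not 1")
    if np.any(ps.initial_state_distribution < 0):
        errors.append("economics.initial_state_distribution: negative mass")

    if errors:
        raise ConfigError("parameter validation failed:\n  " + "\n  ".join(errors))


# ---------------------------------------------------------------------------
# Sampling (probabilistic sensitivity analysis support)
# ---------------------------------------------------------------------------


def iter_params(ps: ParameterSet) -> Iterator[tuple[str, Param]]:
    """Yield every (dotted-path, Param) in a fixed, documented order."""
    tr = ps.transition
    for name in ("normal_to_pre", "pre_to_stage1", "stage1_to_stage2", "pre_to_normal"):
        yield f"transition.{name}", getattr(tr, name)
    for comp in COMPLICATIONS:
        block = ps.hazards[comp]
        for key in ("normal", "pre", "stage1", "stage2", "mortality_immediate", "mortality_yearly"):
            yield f"hazards.{comp}.{key}", getattr(block, key)
    for key in COST_KEYS:
        yield f"costs.{key}", ps.costs[key]
    for name in ("lifestyle", "screening", "medication"):
        yield f"compliance.{name}", getattr(ps.compliance, name)
    yield "economics.discount_rate", ps.discount_rate


def _set_by_path(ps: ParameterSet, path: str, param: Param) -> None:
    parts = path.split(".")
    obj = {"transition": ps.transition, "hazards": ps.hazards, "costs": ps.costs,
           "compliance": ps.compliance, "economics": ps}[parts[0]]
    if parts[0] == "hazards":
        obj = ps.hazards[parts[1]]
        setattr(obj, parts[2], param)
    elif parts[0] == "economics":
        ps.discount_rate = param
    else:
        setattr(obj, parts[1], param)


def sample_parameter_set(ps: ParameterSet, seed) -> ParameterSet:
    """One Monte-Carlo draw of every distributed parameter.

    ``seed`` may be an integer, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`.  Point-mass parameters pass through
    unchanged; identical seeds give identical draws (a counter-based Philox
    generator underlies integer seeds, so results are platform-stable).

    If the sampled pre-hypertension exits (progression + regression) exceed
    1, both are renormalised to sum to 1 and a warning is emitted.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    elif isinstance(seed, np.random.SeedSequence):
        rng = np.random.Generator(np.random.Philox(seed))
    else:
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(int(seed))))

    out = ps.copy()
    for path, param in list(iter_params(out)):
        _set_by_path(out, path, param.sampled(rng))

    # discount rate sampled from Triangular(0, .03, .05) is within bounds by
    # construction; beta draws are within [0,1].  Only the shared multinomial
    # row of the pre-hypertension state can become invalid.
    tr = out.transition
    s = tr.pre_to_stage1.value + tr.pre_to_normal.value
    if s > 1.0:
        warnings.warn(
            f"sampled pre-hypertension exit probabilities sum to {s:.4f} > 1; renormalising",
            RuntimeWarning,
            stacklevel=2,
        )
        tr.pre_to_stage1 = dataclasses.replace(tr.pre_to_stage1, value=tr.pre_to_stage1.value / s)
        tr.pre_to_normal = dataclasses.replace(tr.pre_to_normal, value=tr.pre_to_normal.value / s)

    validate_parameter_set(out, base_case=False)
    return out


# ---------------------------------------------------------------------------
# Round-trip serialisation
# ---------------------------------------------------------------------------


def _dist_to_node(d: Distribution):
    if d.kind == "beta":
        return {"beta": list(d.params)}
    if d.kind == "triangular":
        return {"triangular": list(d.params)}
    return {"point": d.params[0]}


def _param_to_node(p: Param):
    if p.dist.kind == "point" and not p.assumption and not p.source:
        return p.value
    node = {"value": p.value}
    if p.dist.kind != "point":
        node["dist"] = _dist_to_node(p.dist)
    if p.assumption:
        node["assumption"] = True
    if p.source:
        node["source"] = p.source
    return node


def to_dict(ps: ParameterSet) -> dict:
    """The configuration-file dictionary representation of a parameter set."""
    d = {
        "transition": {k: _param_to_node(getattr(ps.transition, k))
                       for k in ("normal_to_pre", "pre_to_stage1",
                                 "stage1_to_stage2", "pre_to_normal")},
        "hazards": {comp: {k: _param_to_node(getattr(ps.hazards[comp], k))
                           for k in ("normal", "pre", "stage1", "stage2",
                                     "mortality_immediate", "mortality_yearly")}
                    for comp in COMPLICATIONS},
        "costs": {k: _param_to_node(ps.costs[k]) for k in COST_KEYS},
        "utilities": {"state": dict(ps.utilities.state),
                      "complication": dict(ps.utilities.complication),
                      "combination_rule": ps.utilities.combination_rule},
        "compliance": {k: _param_to_node(getattr(ps.compliance, k))
                       for k in ("lifestyle", "screening", "medication")},
        "efficacy": {"sbp_reduction": dict(ps.efficacy.sbp_reduction),
                     "dbp_reduction": dict(ps.efficacy.dbp_reduction)},
        "economics": {
            "discount_rate": _param_to_node(ps.discount_rate),
            "horizon_years": ps.horizon_years,
            "initial_state_distribution": {
                s: float(v) for s, v in zip(STATES, ps.initial_state_distribution)},
        },
        "care_model": {
            "mi_visits_per_year": ps.care.mi_visits_per_year,
            "stroke_visits_per_year": ps.care.stroke_visits_per_year,
            "htn_visits_per_year": dict(ps.care.htn_visits_per_year),
            "htn_admissions_per_year": dict(ps.care.htn_admissions_per_year),
        },
    }
    if ps.risk.covariates or ps.risk.intercept or ps.risk.cutoffs:
        d["risk_model"] = {
            "intercept": ps.risk.intercept,
            "modify_regression": ps.risk.modify_regression,
            "covariates": {
                c.name: {"distribution": c.distribution, "weight": c.weight,
                         **({"mu": c.mu, "sigma": c.sigma} if c.distribution == "normal"
                            else {"p": c.p})}
                for c in ps.risk.covariates},
            **({"cutoffs": list(ps.risk.cutoffs)} if ps.risk.cutoffs else {}),
        }
    return d


def dump_parameters(ps: ParameterSet, path) -> None:
    """Write a parameter set back to YAML; point values round-trip exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(ps), fh, sort_keys=False)


def default_config_path() -> Path:
    """Path of the bundled base-case configuration file."""
    return Path(str(resources.files("htncea").joinpath("data/default_config.yaml")))


def load_default_parameters(preset: str = "table1") -> ParameterSet:
    """Load the bundled base-case configuration."""
    return load_parameters(default_config_path(), preset=preset)
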
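"""Prevention strategies and their effect on transition and complication hazards.

Four strategies are compared:

* **usual care** — no preventive programme; states receive routine clinical
  management only.
* **population-wide** — lifestyle modification offered to every state below
  stage II, irrespective of individual risk.
* **high-risk** — prophylactic drug plus education for stage I and stage II
  only (the classic threshold rule).
* **personalized** — escalating bundles by risk group: low-risk individuals
  get screening and low-intensity lifestyle advice, mid-risk mid-intensity
  lifestyle plus a regular checkup, high-risk full lifestyle modification,
  a prophylactic drug and an advanced checkup.  Stage II patients receive
  drug treatment in every group.

A bundle's blood-pressure reduction is converted to a hazard ratio by the
log-linear rule HR = 2^(−ΔSBP/20) (risk halves per 20 mm Hg systolic
reduction), diluted to the population level by all-or-nothing compliance,
and applied on the rate scale to progression probabilities and complication
hazards of the covered states.  Awareness-type bundles (lifestyle,
screening, checkups) cannot lower blood pressure in clinically overt
stage II disease; only drug treatment acts there.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .natural_history import GROUPS, scale_probability
from .parameters import COMPLICATIONS, STATES, Param, ParameterSet

__all__ = [
    "Bundle",
    "BUNDLES",
    "StrategySpec",
    "STRATEGY_NAMES",
    "default_strategies",
    "get_strategy",
    "bp_reduction_to_hazard_ratio",
    "effective_hazard_ratio",
    "apply_strategy",
]

STRATEGY_NAMES = ("usual_care", "population_wide", "high_risk", "personalized")


@dataclass(frozen=True)
class Bundle:
    """One intervention component: its cost keys, effect kind and compliance key.

    ``kind`` is ``"lifestyle"``/``"screening"`` (awareness-type blood-pressure
    effect), ``"drug"`` (pharmacological effect, also active in stage II) or
    ``"cost_only"`` (no blood-pressure effect, e.g. checkup add-ons).
    """

    name: str
    cost_keys: tuple
    kind: str
    compliance_key: str | None


BUNDLES: dict[str, Bundle] = {
    "lifestyle_low": Bundle("lifestyle_low", ("lifestyle_low",), "lifestyle", "lifestyle"),
    "lifestyle_mid": Bundle("lifestyle_mid", ("lifestyle_mid",), "lifestyle", "lifestyle"),
    "lifestyle_full": Bundle("lifestyle_full", ("lifestyle_full",), "lifestyle", "lifestyle"),
    "screening": Bundle("screening", ("screening",), "screening", "screening"),
    "education": Bundle("education", ("screening",), "screening", "screening"),
    "checkup_regular": Bundle("checkup_regular", ("checkup_regular",), "cost_only", None),
    "checkup_advanced": Bundle("checkup_advanced", ("checkup_advanced",), "cost_only", None),
    "drug": Bundle("drug", ("drug",), "drug", "medication"),
}


@dataclass(frozen=True)
class StrategySpec:
    """A prevention strategy: a rule mapping (state, risk group) to bundles."""

    name: str
    #: mapping (state, group) -> tuple of bundle names
    assignment: Mapping

    def bundles(self, state: str, group: str | None) -> tuple:
        names = self.assignment.get((state, group or "mid"), ())
        unknown = [n for n in names if n not in BUNDLES]
        if unknown:
            raise KeyError(f"unknown bundle key(s) {unknown} in strategy {self.name!r}")
        return tuple(BUNDLES[n] for n in names)


def _grid(per_state: Callable[[str, str], tuple]) -> dict:
    return {(s, g): per_state(s, g) for s in STATES for g in GROUPS}


def default_strategies(overrides: Mapping | None = None) -> dict[str, StrategySpec]:
    """The four built-in strategies, optionally overridden from config.

    ``overrides`` mirrors the config block ``strategies``: per strategy
    either ``{bundles: [...], states: [...]}`` (group-independent) or a
    ``{low: [...], mid: [...], high: [...]}`` grid applied to states below
    stage II.
    """
    strategies = {
        "usual_care": StrategySpec("usual_care", _grid(lambda s, g: ())),
        "population_wide": StrategySpec(
            "population_wide",
            _grid(lambda s, g: ("lifestyle_mid",) if s != "stage2" else ()),
        ),
        "high_risk": StrategySpec(
            "high_risk",
            _grid(lambda s, g: ("drug", "education") if s in ("stage1", "stage2") else ()),
        ),
        "personalized": StrategySpec(
            "personalized",
            _grid(lambda s, g: (
                ("drug",) if s == "stage2" else
                {"low": ("screening", "lifestyle_low"),
                 "mid": ("lifestyle_mid", "checkup_regular"),
                 "high": ("lifestyle_full", "drug", "checkup_advanced")}[g]
            )),
        ),
    }
    for name, spec in (overrides or {}).items():
        if name not in strategies:
            raise KeyError(f"unknown strategy {name!r}")
        if "bundles" in spec:
            states = tuple(spec.get("states", [s for s in STATES if s != "stage2"]))
            assignment = _grid(lambda s, g: tuple(spec["bundles"]) if s in states else ())
        else:
            assignment = _grid(lambda s, g: (
                tuple(spec.get("stage2", ["drug"])) if s == "stage2"
                else tuple(spec.get(g, []))))
        strategies[name] = StrategySpec(name, assignment)
    return strategies


def get_strategy(name: str, overrides: Mapping | None = None) -> StrategySpec:
    strategies = default_strategies(overrides)
    if name not in strategies:
        raise KeyError(f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}")
    return strategies[name]


def bp_reduction_to_hazard_ratio(delta_sbp: float) -> float:
    """Hazard ratio from a systolic blood-pressure reduction.

    HR = 2^(−ΔSBP/20): risk halves for every 20 mm Hg systolic lowering,
    the standard log-linear epidemiological relation.
    """
    if delta_sbp < 0:
        raise ValueError(f"blood-pressure reduction must be >= 0, got {delta_sbp}")
    return float(2.0 ** (-delta_sbp / 20.0))


def effective_hazard_ratio(hr: float, compliance: float) -> float:
    """Population-level hazard ratio under all-or-nothing compliance.

    Compliers experience ``hr``; non-compliers experience 1; the cohort-level
    ratio is the compliance-weighted mixture ``c·hr + (1−c)``.
    """
    if not (0.0 < hr <= 1.0):
        raise ValueError(f"hazard ratio must be in (0, 1], got {hr}")
    if not (0.0 <= compliance <= 1.0):
        raise ValueError(f"compliance must be in [0, 1], got {compliance}")
    return compliance * hr + (1.0 - compliance)


def _state_multiplier(ps: ParameterSet, bundles: tuple, state: str) -> float:
    """Combined effective hazard-ratio multiplier for one state.

    At most one awareness-type effect and one drug effect apply per state
    (a second lifestyle/checkup bundle adds cost, not extra blood-pressure
    lowering); their population-level hazard ratios multiply.
    """
    dsbp = ps.efficacy.sbp_reduction[state]
    mult = 1.0
    awareness = [b for b in bundles if b.kind in ("lifestyle", "screening")]
    if awareness and state != "stage2" and dsbp > 0:
        b = next((x for x in awareness if x.kind == "lifestyle"), awareness[0])
        hr = bp_reduction_to_hazard_ratio(dsbp)
        c = getattr(ps.compliance, b.compliance_key).value
        mult *= effective_hazard_ratio(hr, c)
    if any(b.kind == "drug" for b in bundles) and dsbp > 0:
        hr = bp_reduction_to_hazard_ratio(dsbp)
        c = ps.compliance.medication.value
        mult *= effective_hazard_ratio(hr, c)
    return mult


def apply_strategy(ps: ParameterSet, strategy: StrategySpec,
                   group: str | None = None) -> ParameterSet:
    """Strategy-modified parameter set for one risk group.

    Progression probabilities out of each covered state and its complication
    hazards are scaled on the rate scale by the state's combined effective
    hazard ratio; the pre→normal regression is never boosted.  Annual bundle
    costs are attached per state (charged to every targeted person,
    compliant or not — a programme cost).
    """
    out = ps.copy()
    multipliers = {}
    costs = np.zeros(4)
    for i, state in enumerate(STATES):
        bundles = strategy.bundles(state, group)
        multipliers[state] = _state_multiplier(ps, bundles, state)
        seen = set()
        for b in bundles:
            for key in b.cost_keys:
                if key not in seen:  # shared cost items charged once
                    seen.add(key)
                    costs[i] += ps.costs[key].value
    out.intervention_cost_per_state = out.intervention_cost_per_state + costs

    def scaled(param: Param, m: float) -> Param:
        return dataclasses.replace(param, value=scale_probability(param.value, m))

    tr = out.transition
    tr.normal_to_pre = scaled(tr.normal_to_pre, multipliers["normal"])
    tr.pre_to_stage1 = scaled(tr.pre_to_stage1, multipliers["pre"])
    tr.stage1_to_stage2 = scaled(tr.stage1_to_stage2, multipliers["stage1"])
    # regression pre→normal deliberately untouched

    for comp in COMPLICATIONS:
        block = out.hazards[comp]
        for state in STATES:
            setattr(block, state, scaled(getattr(block, state), multipliers[state]))
    return out
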
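"""Synthetic inputs: covariate profiles, risk groups, and oracle toy models.

The underlying cohort data behind the published transition estimates is not
public, so everything the pipeline consumes is generated here: individual
risk-factor profiles with a known log-linear score structure (standing in
for community-screening data), the tertile risk groups they induce, and
tiny parameter sets with closed-form behaviour used as oracles by the test
suite.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .natural_history import stratify
from .parameters import (
    CareModel,
    Compliance,
    ComplicationHazards,
    CostSchedule,
    CovariateSpec,
    Distribution,
    Efficacy,
    HazardBlock,
    Param,
    ParameterSet,
    RiskModel,
    TransitionRates,
    UtilitySchedule,
    COST_KEYS,
    STATES,
)

__all__ = [
    "SyntheticCohortSpec",
    "generate_profiles",
    "make_risk_groups",
    "generate_toy_model",
    "make_reference_run",
]


@dataclass
class SyntheticCohortSpec:
    """Recipe for a synthetic risk-factor cohort.

    Default covariates follow the usual hypertension risk factors —
    standardised age and body-mass index, sex, smoking — with illustrative
    weights (not estimates from any data set).
    """

    n: int = 10_000
    covariates: list = field(default_factory=lambda: [
        CovariateSpec("age_z", "normal", weight=0.30),
        CovariateSpec("male", "bernoulli", weight=0.20, p=0.5),
        CovariateSpec("bmi_z", "normal", weight=0.25),
        CovariateSpec("smoker", "bernoulli", weight=0.40, p=0.3),
    ])
    intercept: float = -0.22
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        for c in self.covariates:
            if c.distribution == "normal" and c.sigma < 0:
                raise ValueError(f"covariate {c.name}: sigma must be >= 0")
            if c.distribution == "bernoulli" and not (0 <= c.p <= 1):
                raise ValueError(f"covariate {c.name}: p must be in [0, 1]")

    @classmethod
    def from_risk_model(cls, risk: RiskModel, n: int = 10_000,
                        seed: int = 0) -> "SyntheticCohortSpec":
        return cls(n=n, covariates=list(risk.covariates) or cls().covariates,
                   intercept=risk.intercept, seed=seed)


def generate_profiles(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw ``spec.n`` covariate profiles and their true risk scores.

    Returns a frame with one column per covariate plus ``score`` (the exact
    log-linear score under the spec's true weights).  Reproducible: the same
    spec (including seed) always yields the same frame.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(int(spec.seed))))
    data = {}
    for c in spec.covariates:
        if c.distribution == "normal":
            data[c.name] = rng.normal(c.mu, c.sigma, spec.n)
        else:
            data[c.name] = rng.binomial(1, c.p, spec.n).astype(float)
    df = pd.DataFrame(data)
    df.insert(0, "id", np.arange(spec.n))
    score = np.full(spec.n, float(spec.intercept))
    for c in spec.covariates:
        score += c.weight * df[c.name].to_numpy()
    df["score"] = score
    return df


def make_risk_groups(profiles: pd.DataFrame, cutoffs=None):
    """Stratify profiles into low/mid/high groups and summarise each group.

    Without explicit cutoffs the empirical tertiles of the score are used
    (the three-colour risk grid).  Returns ``(profiles_with_group, groups)``
    where ``groups`` is the list of ``{"label", "weight", "score"}`` dicts
    consumed by the cohort engine — ``score`` being the group mean.
    """
    scores = profiles["score"].to_numpy()
    if cutoffs is None:
        cutoffs = tuple(np.quantile(scores, [1 / 3, 2 / 3]))
    labels = stratify(scores, cutoffs)
    out = profiles.copy()
    out["group"] = labels
    groups = []
    for label in ("low", "mid", "high"):
        mask = labels == label
        weight = float(mask.mean())
        groups.append({"label": label, "weight": weight,
                       "score": float(scores[mask].mean()) if mask.any() else 0.0})
    return out, groups


# ---------------------------------------------------------------------------
# Oracle toy models
# ---------------------------------------------------------------------------


def _point(v: float) -> Param:
    return Param(float(v))


def _zero_hazards() -> ComplicationHazards:
    def blk():
        return HazardBlock(*(_point(0.0) for _ in range(6)))
    return ComplicationHazards(ami=blk(), stroke=blk(), esrd=blk())


def _zero_costs() -> CostSchedule:
    return CostSchedule(**{k: _point(0.0) for k in COST_KEYS})


def _unit_utilities() -> UtilitySchedule:
    return UtilitySchedule(state={s: 1.0 for s in STATES},
                           complication={"ami": 1.0, "stroke": 1.0, "esrd": 1.0})


def _toy_base(initial) -> ParameterSet:
    return ParameterSet(
        transition=TransitionRates(_point(0.0), _point(0.0), _point(0.0), _point(0.0)),
        hazards=_zero_hazards(),
        costs=_zero_costs(),
        utilities=_unit_utilities(),
        compliance=Compliance(_point(0.6), _point(0.7), _point(0.5)),
        efficacy=Efficacy(sbp_reduction={s: 0.0 for s in STATES}),
        discount_rate=_point(0.0),
        horizon_years=20,
        initial_state_distribution=np.asarray(initial, dtype=float),
        care=CareModel(mi_visits_per_year=0.0, stroke_visits_per_year=0.0,
                       htn_visits_per_year={}, htn_admissions_per_year={}),
    )


def generate_toy_model(name: str, p: float = 0.1, h: float = 0.2,
                       m: float = 0.15) -> ParameterSet:
    """Tiny parameter sets with closed-form behaviour, for oracle tests.

    ``"frozen"``
        All transitions and hazards zero: the cohort never moves and nobody
        dies.
    ``"geometric"``
        Everyone starts pre-hypertensive with a single transition
        pre→stage I of probability ``p``; stage I occupancy after t cycles
        is exactly 1 − (1−p)^t.
    ``"single_complication"``
        Everyone starts in stage II with one myocardial-infarction hazard
        ``h`` and immediate case fatality ``m``; first-cycle deaths equal
        h·m exactly.
    """
    if name == "frozen":
        return _toy_base([0.25, 0.25, 0.25, 0.25])
    if name == "geometric":
        ps = _toy_base([0.0, 1.0, 0.0, 0.0])
        ps.transition = TransitionRates(_point(0.0), _point(p), _point(0.0), _point(0.0))
        return ps
    if name == "single_complication":
        ps = _toy_base([0.0, 0.0, 0.0, 1.0])
        ps.hazards.ami = HazardBlock(
            normal=_point(h), pre=_point(h), stage1=_point(h), stage2=_point(h),
            mortality_immediate=_point(m), mortality_yearly=_point(0.0),
        )
        return ps
    raise ValueError(f"unknown toy model {name!r}; "
                     "expected 'frozen', 'geometric' or 'single_complication'")


def make_reference_run(seed: int, ps: ParameterSet | None = None,
                       n_profiles: int = 10_000, comparator: str = "usual_care",
                       strategy_overrides=None) -> pd.DataFrame:
    """Deterministic comparison table of all four strategies.

    Runs the bundled assumption-flagged configuration (or ``ps``) through
    the full pipeline — synthetic profiles, tertile risk groups, strategy
    application, cohort simulation, economics — and returns the rounded
    comparison table.  A regression fixture for this package's own
    configuration, not a reproduction of any published totals.
    """
    from .economics import comparison_table
    from .engine import evaluate_strategies
    from .interventions import default_strategies
    from .parameters import load_default_parameters

    if ps is None:
        ps = load_default_parameters()
    spec = SyntheticCohortSpec.from_risk_model(ps.risk, n=n_profiles, seed=seed)
    _, groups = make_risk_groups(generate_profiles(spec), ps.risk.cutoffs)
    strategies = list(default_strategies(strategy_overrides).values())
    results = evaluate_strategies(ps, strategies, groups)
    return comparison_table(results, comparator=comparator)
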
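"""Annual-cycle deterministic cohort engine over disease × complication × vital states.

The cohort occupies 4 disease states crossed with the 8 subsets of the three
complications (myocardial infarction, stroke, end-stage renal disease) while
alive, plus an absorbing dead state.  Each one-year cycle proceeds in a
fixed order: (1) disease-state transition; (2) complication events drawn per
current disease state with independent hazards (their products generate the
combined complication nodes); (3) immediate case fatality applied to
incident events; (4) annual mortality applied to prevalent complication
carriers.  Complications persist for life.

Costs and utilities are counted at cycle end for cycles 1..T (no half-cycle
correction); cycle 0 holds the initial distribution only.  Terminal-care
cost is charged once in the cycle of death.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .economics import CEResult
from .interventions import StrategySpec, apply_strategy
from .natural_history import build_transition_matrix, personalize_rates
from .parameters import COMPLICATIONS, STATES, ParameterSet

__all__ = [
    "CohortTrace",
    "run_cohort",
    "discount_factor",
    "accumulate",
    "evaluate_strategy",
    "evaluate_strategies",
]

_NC = len(COMPLICATIONS)  # bit 0 = AMI, bit 1 = stroke, bit 2 = ESRD
_NK = 1 << _NC

#: for each carried-complication mask, the subsets of the remaining
#: complications that can occur within one cycle
_EVENT_SETS = {
    k: [tuple(a) for r in range(_NC + 1)
        for a in combinations([c for c in range(_NC) if not k & (1 << c)], r)]
    for k in range(_NK)
}


def _mask_has(k: int, c: int) -> bool:
    return bool(k & (1 << c))


@dataclass
class CohortTrace:
    """Per-cycle cohort occupancy and cost/utility flows.

    ``occupancy[t, d, k]`` is the alive mass in disease state ``d`` carrying
    complication set ``k`` (bitmask over AMI/stroke/ESRD) at cycle ``t``;
    ``dead[t]`` the cumulative dead mass.  Flows at index 0 are zero by the
    end-of-cycle counting convention.
    """

    occupancy: np.ndarray  # (T+1, 4, 8)
    dead: np.ndarray  # (T+1,)
    cost_flow: np.ndarray  # (T+1,)
    utility_flow: np.ndarray  # (T+1,)

    @property
    def horizon(self) -> int:
        return len(self.dead) - 1

    def disease_occupancy(self) -> np.ndarray:
        """Alive mass per disease state, shape (T+1, 4)."""
        return self.occupancy.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle trace (cycle, state, complications, occupancy) plus flows."""
        records = []
        for t in range(self.horizon + 1):
            for d, state in enumerate(STATES):
                for k in range(_NK):
                    mass = self.occupancy[t, d, k]
                    if mass == 0 and k:
                        continue
                    comps = "+".join(c for i, c in enumerate(COMPLICATIONS)
                                     if _mask_has(k, i)) or "none"
                    records.append((t, state, comps, mass,
                                    self.cost_flow[t], self.utility_flow[t]))
            records.append((t, "dead", "none", self.dead[t],
                            self.cost_flow[t], self.utility_flow[t]))
        return pd.DataFrame(records, columns=["cycle", "state", "complications",
                                              "occupancy", "cost_flow", "utility_flow"])


class _CycleOperator:
    """Precomputed one-cycle update tensors for a fixed parameter set."""

    def __init__(self, ps: ParameterSet):
        self.ps = ps
        self.M = build_transition_matrix(ps.transition)
        h = np.array([ps.hazards[c].state_probs() for c in COMPLICATIONS]).T  # (4, 3)
        m_imm = np.array([ps.hazards[c].mortality_immediate.value for c in COMPLICATIONS])
        m_yr = np.array([ps.hazards[c].mortality_yearly.value for c in COMPLICATIONS])

        self.T_alive = np.zeros((4, _NK, _NK))
        self.death = np.zeros((4, _NK))
        self.incident = np.zeros((4, _NK, _NC))  # expected incident events of c
        for d in range(4):
            for k in range(_NK):
                prev_surv = np.prod([1.0 - m_yr[c] for c in range(_NC) if _mask_has(k, c)])
                free = [c for c in range(_NC) if not _mask_has(k, c)]
                for A in _EVENT_SETS[k]:
                    pA = 1.0
                    for c in free:
                        pA *= h[d, c] if c in A else 1.0 - h[d, c]
                    s_imm = np.prod([1.0 - m_imm[c] for c in A]) if A else 1.0
                    newk = k
                    for c in A:
                        newk |= 1 << c
                    self.T_alive[d, k, newk] += pA * s_imm * prev_surv
                    self.death[d, k] += pA * (1.0 - s_imm * prev_surv)
                    for c in A:
                        self.incident[d, k, c] += pA
        # surviving-mass fraction per source cell (for prevalent-carrier costs)
        self.alive_frac = self.T_alive.sum(axis=2)  # (4, 8)

        # per-cell utility weights
        u_state = np.array([ps.utilities.state[s] for s in STATES])
        u_comp = np.array([ps.utilities.complication[c] for c in COMPLICATIONS])
        u_mask = np.ones(_NK)
        for k in range(_NK):
            ws = [u_comp[c] for c in range(_NC) if _mask_has(k, c)]
            if ws:
                u_mask[k] = min(ws) if ps.utilities.combination_rule == "minimum" else np.prod(ws)
        self.U = u_state[:, None] * u_mask[None, :]  # (4, 8)

        c = ps.costs
        care = ps.care
        self.cost_admission = np.array([c.mi_admission.value, c.stroke_admission.value, 0.0])
        self.cost_prevalent = np.array([
            c.mi_visit.value * care.mi_visits_per_year,
            c.stroke_visit.value * care.stroke_visits_per_year,
            0.0,
        ])
        self.cost_carrier = np.array([0.0, 0.0, c.esrd_annual.value])
        self.cost_state = np.array([
            c.htn_visit.value * care.htn_visits_per_year.get(s, 0.0)
            + c.htn_admission.value * care.htn_admissions_per_year.get(s, 0.0)
            for s in STATES
        ]) + ps.intervention_cost_per_state
        self.cost_terminal = c.terminal_care.value
        self.carrier_mask = np.array([[float(_mask_has(k, ci)) for k in range(_NK)]
                                      for ci in range(_NC)])  # (3, 8)

    def step(self, occ: np.ndarray) -> tuple[np.ndarray, float, float, float]:
        """One annual cycle: returns (new occupancy, deaths, cost flow, utility flow)."""
        occ1 = np.einsum("ds,dk->sk", self.M, occ)  # disease transition
        occ2 = np.einsum("dk,dkl->dl", occ1, self.T_alive)  # complication events + mortality
        deaths = float(np.einsum("dk,dk->", occ1, self.death))
        inc = np.einsum("dk,dkc->c", occ1, self.incident)  # incident events (incl. fatal)
        prev_surv = np.einsum("dk,dk,ck->c", occ1, self.alive_frac, self.carrier_mask)
        carriers_end = np.einsum("dk,ck->c", occ2, self.carrier_mask)

        cost = float(
            inc @ self.cost_admission
            + prev_surv @ self.cost_prevalent
            + carriers_end @ self.cost_carrier
            + occ2.sum(axis=1) @ self.cost_state
            + deaths * self.cost_terminal
        )
        utility = float(np.sum(occ2 * self.U))
        return occ2, deaths, cost, utility


def run_cohort(ps: ParameterSet, strategy: StrategySpec | None = None,
               group: str | None = None, horizon: int | None = None) -> CohortTrace:
    """Simulate the cohort for one (strategy-modified) parameter set.

    If ``strategy`` is given it is applied first (for risk group ``group``);
    otherwise ``ps`` is taken as already modified.  The trace spans cycles
    0..T with the initial state distribution at cycle 0, no complications
    and no dead mass.
    """
    if strategy is not None:
        ps = apply_strategy(ps, strategy, group)
    T = int(horizon if horizon is not None else ps.horizon_years)
    if T < 1:
        raise ValueError(f"horizon must be >= 1, got {T}")
    op = _CycleOperator(ps)

    occ = np.zeros((T + 1, 4, _NK))
    dead = np.zeros(T + 1)
    cost = np.zeros(T + 1)
    util = np.zeros(T + 1)
    occ[0, :, 0] = ps.initial_state_distribution

    for t in range(1, T + 1):
        occ[t], deaths, cost[t], util[t] = op.step(occ[t - 1])
        dead[t] = dead[t - 1] + deaths
        total = occ[t].sum() + dead[t]
        if abs(total - 1.0) > 1e-9:
            raise RuntimeError(
                f"cycle {t}: occupancy not conserved (total {total!r}); "
                "a transition row is not stochastic"
            )
    return CohortTrace(occupancy=occ, dead=dead, cost_flow=cost, utility_flow=util)


def discount_factor(rate: float, t: int) -> float:
    """Present-value factor (1 + rate)^(−t); cycle-0 flows are undiscounted."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if t < 0:
        raise ValueError(f"cycle index must be >= 0, got {t}")
    return float((1.0 + rate) ** (-t))


def accumulate(trace: CohortTrace, rate: float, strategy: str = "") -> CEResult:
    """Discounted total cost and QALYs of a cohort trace."""
    t = np.arange(trace.horizon + 1)
    df = (1.0 + rate) ** (-t.astype(float))
    cost = float(trace.cost_flow @ df)
    qaly = float(trace.utility_flow @ df)
    return CEResult(strategy=strategy, cost=cost, qaly=qaly,
                    horizon=trace.horizon, discount_rate=rate)


def evaluate_strategy(ps: ParameterSet, strategy: StrategySpec,
                      groups=None) -> CEResult:
    """Population-level discounted cost and QALYs of one strategy.

    ``groups`` is a list of ``{"label", "weight", "score"}`` risk groups; the
    natural history of each group is personalized through its mean risk
    score, the strategy's group-specific bundles are applied, and results
    are weighted by group size.  ``None`` runs a single average-risk cohort.
    """
    if groups is None:
        groups = [{"label": None, "weight": 1.0, "score": 0.0}]
    wsum = sum(g["weight"] for g in groups)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"group weights must sum to 1, got {wsum}")
    cost = qaly = 0.0
    rate = ps.discount_rate.value
    for g in groups:
        psg = ps.copy()
        psg.transition = personalize_rates(ps.transition, g["score"],
                                           ps.risk.modify_regression)
        trace = run_cohort(psg, strategy, g["label"])
        res = accumulate(trace, rate)
        cost += g["weight"] * res.cost
        qaly += g["weight"] * res.qaly
    return CEResult(strategy=strategy.name, cost=cost, qaly=qaly,
                    horizon=ps.horizon_years, discount_rate=rate)


def evaluate_strategies(ps: ParameterSet, strategies, groups=None) -> list[CEResult]:
    """Evaluate several strategies on the same parameter set and risk groups."""
    return [evaluate_strategy(ps, s, groups) for s in strategies]
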
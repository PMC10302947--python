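"""Probabilistic sensitivity analysis: Monte-Carlo over parameter uncertainty.

Each replicate redraws every distributed parameter from its Beta/Triangular
distribution and re-evaluates all strategies on the same draw (common random
numbers, so strategy increments are not inflated by between-replicate
noise).  The replicate cloud of (Δcost, ΔQALY) pairs populates the
four-quadrant cost-effectiveness plane; the cost-effectiveness
acceptability curve (CEAC) gives, per willingness-to-pay value, the
fraction of replicates in which a strategy has the higher net monetary
benefit than the comparator (ties counted half, so a two-way CEAC pair sums
to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import classify
from .engine import evaluate_strategy
from .parameters import ParameterSet, sample_parameter_set

__all__ = [
    "PSAResults",
    "CEAC",
    "run_psa",
    "compute_ceac",
    "export_ce_plane",
    "default_wtp_grid",
    "plot_ce_plane",
    "plot_ceac",
]

#: Quadrant labels of the CE plane in scatter exports (x = ΔQALY, y = Δcost).
_QUADRANT = {"dominant": "SE", "dominated": "NW",
             "trade_off_ne": "NE", "trade_off_sw": "SW"}


@dataclass
class PSAResults:
    """Monte-Carlo replicate matrix of discounted (cost, QALY) per strategy."""

    strategies: list  # strategy names, comparator included
    costs: np.ndarray  # (n, S)
    qalys: np.ndarray  # (n, S)
    seed: int
    comparator: str = "usual_care"

    @property
    def n(self) -> int:
        return self.costs.shape[0]

    def _idx(self, name: str) -> int:
        try:
            return self.strategies.index(name)
        except ValueError:
            raise KeyError(f"strategy {name!r} not in PSA results {self.strategies}")

    def increments(self, strategy: str, comparator: str | None = None):
        """Per-replicate (Δcost, ΔQALY) arrays of a strategy vs the comparator."""
        i = self._idx(strategy)
        j = self._idx(comparator or self.comparator)
        return self.costs[:, i] - self.costs[:, j], self.qalys[:, i] - self.qalys[:, j]


@dataclass
class CEAC:
    """Cost-effectiveness acceptability curves on a willingness-to-pay grid."""

    wtp: np.ndarray  # strictly increasing USD/QALY grid
    probability: dict  # strategy -> np.ndarray of P(cost-effective) in [0, 1]
    comparator: str = "usual_care"

    def to_frame(self) -> pd.DataFrame:
        records = [(w, s, p) for s, probs in self.probability.items()
                   for w, p in zip(self.wtp, probs)]
        return pd.DataFrame(records, columns=["wtp", "strategy", "probability"])


def _replicate_rng(seed: int, r: int) -> np.random.Generator:
    # counter-based generator keyed by (master seed, replicate index):
    # platform-stable and independent across replicates
    return np.random.Generator(np.random.Philox(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(r),))))


def run_psa(ps: ParameterSet, strategies, n: int, seed: int,
            groups=None, comparator: str = "usual_care") -> PSAResults:
    """Monte-Carlo PSA: ``n`` replicates of all strategies under shared draws.

    Replicate ``r`` evaluates every strategy on the parameter set sampled
    with the generator keyed by ``(seed, r)``; identical inputs give
    identical results.  ``groups`` are the fixed risk groups (the risk-score
    structure is not part of the sampled uncertainty).
    """
    if n < 1:
        raise ValueError(f"replicate count must be >= 1, got {n}")
    strategies = list(strategies)
    names = [s.name for s in strategies]
    costs = np.empty((n, len(strategies)))
    qalys = np.empty((n, len(strategies)))
    for r in range(n):
        draw = sample_parameter_set(ps, _replicate_rng(seed, r))
        for j, strat in enumerate(strategies):
            res = evaluate_strategy(draw, strat, groups)
            costs[r, j] = res.cost
            qalys[r, j] = res.qaly
    return PSAResults(strategies=names, costs=costs, qalys=qalys,
                      seed=int(seed), comparator=comparator)


def default_wtp_grid(wtp_max: float = 300_000.0, step: float = 10_000.0) -> np.ndarray:
    """Willingness-to-pay grid 0..wtp_max in ``step`` increments (USD/QALY)."""
    return np.arange(0.0, wtp_max + step / 2, step)


def compute_ceac(psa: PSAResults, wtp_grid=None,
                 comparator: str | None = None) -> CEAC:
    """Acceptability curves of every non-comparator strategy.

    P(cost-effective at λ) is the fraction of replicates in which the
    strategy's net monetary benefit exceeds the comparator's; exact ties
    count one half.
    """
    if psa.n < 1:
        raise ValueError("PSA results are empty")
    wtp = np.asarray(default_wtp_grid() if wtp_grid is None else wtp_grid, dtype=float)
    if wtp.ndim != 1 or len(wtp) == 0 or np.any(np.diff(wtp) <= 0):
        raise ValueError("willingness-to-pay grid must be a strictly increasing vector")
    comparator = comparator or psa.comparator
    probability = {}
    for name in psa.strategies:
        if name == comparator:
            continue
        d_cost, d_qaly = psa.increments(name, comparator)
        # ΔNMB(λ) = λ·ΔQALY − Δcost, one column per grid point
        d_nmb = wtp[None, :] * d_qaly[:, None] - d_cost[:, None]
        probability[name] = ((d_nmb > 0).mean(axis=0) + 0.5 * (d_nmb == 0).mean(axis=0))
    return CEAC(wtp=wtp, probability=probability, comparator=comparator)


def export_ce_plane(psa: PSAResults, comparator: str | None = None) -> pd.DataFrame:
    """Tidy CE-plane scatter: (replicate, strategy, d_cost, d_qaly, quadrant)."""
    if not psa.strategies:
        raise ValueError("PSA results contain no strategies")
    comparator = comparator or psa.comparator
    frames = []
    for name in psa.strategies:
        if name == comparator:
            continue
        d_cost, d_qaly = psa.increments(name, comparator)
        quad = [_QUADRANT[classify(c, q)] for c, q in zip(d_cost, d_qaly)]
        frames.append(pd.DataFrame({
            "replicate": np.arange(psa.n), "strategy": name,
            "d_cost": d_cost, "d_qaly": d_qaly, "quadrant": quad,
        }))
    if not frames:
        raise ValueError("no strategy to compare against the comparator")
    return pd.concat(frames, ignore_index=True)


def plot_ce_plane(psa: PSAResults, path=None, comparator: str | None = None):
    """Scatter the replicate increments on the four-quadrant CE plane."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = export_ce_plane(psa, comparator)
    fig, ax = plt.subplots(figsize=(6, 5))
    for name, sub in table.groupby("strategy"):
        ax.scatter(sub["d_qaly"], sub["d_cost"], s=6, alpha=0.4, label=name)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental QALY")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ceac(ceac: CEAC, path=None):
    """Plot acceptability curves over willingness to pay."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, probs in ceac.probability.items():
        ax.plot(ceac.wtp, probs, label=name)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
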
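"""Deterministic cost-utility comparisons: increments, ICUR, NMB, dominance.

The incremental cost-utility ratio (ICUR) divides the difference in
discounted cost by the difference in discounted QALYs between a strategy
and its comparator (usual care by default).  Net monetary benefit (NMB)
linearises the same decision rule at a willingness-to-pay λ:
NMB = λ·QALY − cost.  A comparison falls in one of the four quadrants of
the cost-effectiveness plane: dominant (cheaper, more effective),
dominated (dearer, less effective), or a north-east / south-west
trade-off.

Negative ICURs (a dominant strategy) are reported verbatim with the
dominance flag; they are not interpretable as prices.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CEResult",
    "CEComparison",
    "incremental",
    "icur",
    "nmb",
    "classify",
    "compare",
    "comparison_table",
]


@dataclass(frozen=True)
class CEResult:
    """Discounted totals of one strategy arm."""

    strategy: str
    cost: float  # USD, discounted
    qaly: float  # QALYs, discounted
    horizon: int | None = None
    discount_rate: float | None = None


@dataclass(frozen=True)
class CEComparison:
    """A strategy against its comparator on the cost-effectiveness plane."""

    comparator: CEResult
    strategy: CEResult
    d_cost: float
    d_qaly: float
    icur: float | None  # None when d_qaly == 0
    quadrant: str  # dominant | dominated | trade_off_ne | trade_off_sw


def _check_settings(a: CEResult, b: CEResult) -> None:
    for attr in ("horizon", "discount_rate"):
        va, vb = getattr(a, attr), getattr(b, attr)
        if va is not None and vb is not None and va != vb:
            raise ValueError(f"mismatched {attr}: {va} vs {vb}")


def incremental(comparator: CEResult, strategy: CEResult) -> tuple[float, float]:
    """(Δcost, ΔQALY) of a strategy relative to its comparator."""
    _check_settings(comparator, strategy)
    return strategy.cost - comparator.cost, strategy.qaly - comparator.qaly


def icur(d_cost: float, d_qaly: float) -> float:
    """Incremental cost-utility ratio Δcost / ΔQALY (USD per QALY).

    Undefined at ΔQALY = 0 — use dominance or NMB language there.
    """
    if d_qaly == 0:
        raise ZeroDivisionError("ICUR undefined for zero QALY increment; "
                                "report dominance or net monetary benefit instead")
    return d_cost / d_qaly


def nmb(result: CEResult, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp``: wtp·QALY − cost."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * result.qaly - result.cost


def classify(d_cost: float, d_qaly: float) -> str:
    """Cost-effectiveness-plane quadrant of an increment pair.

    Strict dominance requires strict inequalities; boundary cases fall into
    the trade-off quadrants ((0, 0) is north-east by convention).
    """
    if d_qaly > 0:
        return "dominant" if d_cost < 0 else "trade_off_ne"
    if d_qaly < 0:
        return "dominated" if d_cost > 0 else "trade_off_sw"
    return "trade_off_ne" if d_cost >= 0 else "trade_off_sw"


def compare(comparator: CEResult, strategy: CEResult) -> CEComparison:
    """Full pairwise comparison: increments, ICUR (if defined) and quadrant."""
    d_cost, d_qaly = incremental(comparator, strategy)
    ratio = icur(d_cost, d_qaly) if d_qaly != 0 else None
    return CEComparison(comparator=comparator, strategy=strategy,
                        d_cost=d_cost, d_qaly=d_qaly, icur=ratio,
                        quadrant=classify(d_cost, d_qaly))


def comparison_table(results, comparator: str = "usual_care",
                     rounded: bool = True) -> pd.DataFrame:
    """Strategy comparison table: cost, QALY, increments, ICUR, quadrant.

    One row per strategy; the comparator row leaves its increment cells
    empty.  With ``rounded`` (default), USD values are rounded to integers
    and QALYs to 4 decimals, the conventional reporting precision.
    """
    by_name = {r.strategy: r for r in results}
    if comparator not in by_name:
        raise ValueError(f"comparator {comparator!r} not among results "
                         f"{sorted(by_name)}")
    base = by_name[comparator]
    rows = []
    for r in results:
        if r.strategy == comparator:
            rows.append((r.strategy, r.cost, r.qaly, None, None, None, ""))
            continue
        c = compare(base, r)
        rows.append((r.strategy, r.cost, r.qaly, c.d_cost, c.d_qaly, c.icur, c.quadrant))
    df = pd.DataFrame(rows, columns=["strategy", "cost", "qaly", "increment_cost",
                                     "increment_qaly", "icur", "quadrant"])
    if rounded:
        for col in ("cost", "increment_cost", "icur"):
            df[col] = pd.Series([None if pd.isna(v) else int(round(v))
                                 for v in df[col]], dtype=object)
        for col in ("qaly", "increment_qaly"):
            df[col] = pd.Series([None if pd.isna(v) else round(float(v), 4)
                                 for v in df[col]], dtype=object)
    return df
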
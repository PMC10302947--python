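"""Four-state natural history of hypertension and state-specific risk scores.

Disease states are normal blood pressure, pre-hypertension, stage I and
stage II hypertension.  Pre-hypertension may regress to normal; once stage I
is entered, regression is no longer possible, and stage II is absorbing
within the disease space.  A log-linear risk score built from individual
covariates multiplies progression rates (proportional-hazards convention),
which is the basis for risk-group stratification and personalized
prevention.
"""

from __future__ import annotations

import dataclasses
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np

from .parameters import TransitionRates

__all__ = [
    "DiseaseState",
    "build_transition_matrix",
    "risk_score",
    "stratify",
    "personalize_rates",
    "scale_probability",
    "GROUPS",
]

#: Risk-group labels in increasing-risk order.
GROUPS = ("low", "mid", "high")


class DiseaseState(IntEnum):
    """The four blood-pressure states, totally ordered by severity."""

    NORMAL = 0
    PRE = 1
    STAGE1 = 2
    STAGE2 = 3


def build_transition_matrix(tr: TransitionRates) -> np.ndarray:
    """Annual 4×4 disease transition matrix.

    Rows/columns follow :class:`DiseaseState` order.  The only permitted
    off-diagonal moves are normal→pre, pre→normal, pre→stage I and
    stage I→stage II; diagonals complete each row to 1.  Stage II is
    absorbing within the disease space.

    Raises
    ------
    ValueError
        If any row's exit probabilities exceed 1 (naming the row).
    """
    p01 = tr.normal_to_pre.value
    p12 = tr.pre_to_stage1.value
    p10 = tr.pre_to_normal.value
    p23 = tr.stage1_to_stage2.value
    for name, exit_sum in (("normal", p01), ("pre", p12 + p10), ("stage1", p23)):
        if exit_sum > 1.0 + 1e-12:
            raise ValueError(f"row '{name}': exit probabilities sum to {exit_sum:.6g} > 1")
    m = np.zeros((4, 4))
    m[0, 0], m[0, 1] = 1.0 - p01, p01
    m[1, 0], m[1, 1], m[1, 2] = p10, 1.0 - p10 - p12, p12
    m[2, 2], m[2, 3] = 1.0 - p23, p23
    m[3, 3] = 1.0
    return m


def risk_score(profile: Mapping[str, float], weights: Mapping[str, float],
               intercept: float = 0.0) -> float:
    """Linear predictor ``intercept + Σ w_i x_i`` of the state-specific risk model.

    ``profile`` and ``weights`` must carry exactly the same covariate names.
    ``exp(score)`` is the multiplicative effect on progression rates.
    """
    unmatched = set(profile) ^ set(weights)
    if unmatched:
        raise ValueError(f"profile/weights name mismatch: {sorted(unmatched)}")
    score = float(intercept) + sum(weights[k] * profile[k] for k in weights)
    if not np.isfinite(score):
        raise ValueError(f"risk score is not finite: {score}")
    return score


def stratify(scores: Sequence[float], cutoffs: Sequence[float]) -> np.ndarray:
    """Assign risk-group labels by two ordered score cutoffs.

    low if score < c1, mid if c1 <= score < c2, high if score >= c2.
    """
    c1, c2 = cutoffs
    if not c1 < c2:
        raise ValueError(f"cutoffs must be strictly increasing, got ({c1}, {c2})")
    scores = np.asarray(scores, dtype=float)
    labels = np.full(scores.shape, "mid", dtype=object)
    labels[scores < c1] = "low"
    labels[scores >= c2] = "high"
    return labels


def scale_probability(p: float, multiplier: float) -> float:
    """Scale an annual probability by a multiplier on the rate scale.

    ``p' = 1 − (1−p)^m`` — the exact effect of multiplying the underlying
    constant hazard by ``m``; stays in [0, 1] for any m ≥ 0, unlike naive
    multiplication.  A unit multiplier is an exact no-op.
    """
    if multiplier == 1.0:
        return float(np.clip(p, 0.0, 1.0))
    return float(np.clip(1.0 - (1.0 - p) ** multiplier, 0.0, 1.0))


def personalize_rates(tr: TransitionRates, score: float,
                      modify_regression: bool = False) -> TransitionRates:
    """Transition rates of an individual (or group) with a given risk score.

    Each progression probability is scaled on the rate scale by
    ``exp(score)``; the pre→normal regression is left unchanged unless
    ``modify_regression`` (in which case the same multiplier applies).
    """
    if not np.isfinite(score):
        raise ValueError(f"risk score must be finite, got {score}")
    m = float(np.exp(score))

    def scaled(param):
        return dataclasses.replace(param, value=scale_probability(param.value, m))

    out = TransitionRates(
        normal_to_pre=scaled(tr.normal_to_pre),
        pre_to_stage1=scaled(tr.pre_to_stage1),
        stage1_to_stage2=scaled(tr.stage1_to_stage2),
        pre_to_normal=scaled(tr.pre_to_normal) if modify_regression else tr.pre_to_normal,
    )
    # a shared multinomial row can overflow under a large multiplier
    s = out.pre_to_stage1.value + out.pre_to_normal.value
    if s > 1.0:
        out.pre_to_stage1 = dataclasses.replace(out.pre_to_stage1,
                                                value=out.pre_to_stage1.value / s)
        out.pre_to_normal = dataclasses.replace(out.pre_to_normal,
                                                value=out.pre_to_normal.value / s)
    return out
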
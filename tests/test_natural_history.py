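"""Transition-matrix construction, risk scores, stratification, personalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htncea.natural_history import (
    build_transition_matrix,
    personalize_rates,
    risk_score,
    scale_probability,
    stratify,
)
from htncea.parameters import Param, TransitionRates


def _rates(n2p=0.0, p2s1=0.0, s12s2=0.0, p2n=0.0):
    return TransitionRates(Param(n2p), Param(p2s1), Param(s12s2), Param(p2n))


def test_zero_rates_give_identity_matrix():
    assert np.array_equal(build_transition_matrix(_rates()), np.eye(4))


def test_pre_row_completed_by_complementarity():
    m = build_transition_matrix(_rates(p2s1=0.1, p2n=0.05))
    assert m[1].tolist() == [0.05, 0.85, 0.10, 0.0]


def test_disallowed_cells_are_exactly_zero():
    m = build_transition_matrix(_rates(0.08, 0.06, 0.05, 0.10))
    # no regression past stage I, no jumps over adjacent states
    forbidden = [(0, 2), (0, 3), (1, 3), (2, 0), (2, 1), (3, 0), (3, 1), (3, 2)]
    for i, j in forbidden:
        assert m[i, j] == 0.0


def test_overfull_row_error_names_the_row():
    with pytest.raises(ValueError, match="'pre'"):
        build_transition_matrix(_rates(p2s1=0.7, p2n=0.5))


@settings(max_examples=100, derandomize=True)
@given(
    n2p=st.floats(0, 1), s12s2=st.floats(0, 1),
    p2s1=st.floats(0, 1), frac=st.floats(0, 1),
)
def test_every_matrix_is_row_stochastic(n2p, s12s2, p2s1, frac):
    p2n = (1.0 - p2s1) * frac  # keeps the pre row feasible
    m = build_transition_matrix(_rates(n2p, p2s1, s12s2, p2n))
    assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(m >= 0)


def test_risk_score_reduces_to_intercept():
    assert risk_score({"a": 0.0, "b": 0.0}, {"a": 1.2, "b": -0.4}, 0.7) == 0.7
    assert risk_score({"a": 3.0, "b": 9.0}, {"a": 0.0, "b": 0.0}, 0.7) == 0.7


def test_risk_score_log_linear_doubling():
    s = risk_score({"x": 1.0}, {"x": math.log(2)}, 0.0)
    assert math.exp(s) == pytest.approx(2.0, rel=1e-12)


def test_risk_score_name_mismatch_lists_unmatched():
    with pytest.raises(ValueError, match="extra"):
        risk_score({"a": 1.0, "extra": 2.0}, {"a": 0.5})


def test_stratify_boundary_convention():
    labels = stratify([-1.0, 0.0, 1.0], (0.0, 0.5))
    assert labels.tolist() == ["low", "mid", "high"]


def test_stratify_all_below_first_cutoff():
    assert set(stratify([-5.0] * 7, (0.0, 1.0))) == {"low"}


def test_stratify_rejects_non_increasing_cutoffs():
    with pytest.raises(ValueError):
        stratify([0.0], (1.0, 1.0))


def test_tertile_cutoffs_split_evenly():
    rng = np.random.Generator(np.random.Philox(7))
    scores = rng.normal(size=1000)
    cutoffs = np.quantile(scores, [1 / 3, 2 / 3])
    labels = stratify(scores, cutoffs)
    counts = {g: int((labels == g).sum()) for g in ("low", "mid", "high")}
    assert abs(counts["low"] - 333) <= 1
    assert abs(counts["mid"] - 334) <= 1
    assert abs(counts["high"] - 333) <= 1
    assert sum(counts.values()) == 1000


def test_personalize_identity_at_zero_score():
    tr = _rates(0.08, 0.06, 0.05, 0.10)
    out = personalize_rates(tr, 0.0)
    assert out.normal_to_pre.value == pytest.approx(0.08, rel=1e-12)
    assert out.pre_to_normal.value == 0.10


def test_personalize_rate_doubling_closed_form():
    out = personalize_rates(_rates(p2s1=0.1), math.log(2))
    assert out.pre_to_stage1.value == pytest.approx(1 - 0.9**2, rel=1e-12)


def test_personalize_extreme_score_saturates_at_one():
    out = personalize_rates(_rates(0.1, 0.1, 0.1, 0.0), 50.0)
    assert out.normal_to_pre.value == pytest.approx(1.0)
    assert out.stage1_to_stage2.value == pytest.approx(1.0)


def test_personalize_leaves_regression_unchanged_by_default():
    tr = _rates(0.08, 0.06, 0.05, 0.10)
    assert personalize_rates(tr, 1.3).pre_to_normal.value == 0.10
    assert personalize_rates(tr, 1.3, modify_regression=True).pre_to_normal.value > 0.10


@settings(max_examples=100, derandomize=True)
@given(p=st.floats(0, 0.5), s1=st.floats(-2, 2), s2=st.floats(-2, 2))
def test_personalize_is_monotone_in_score(p, s1, s2):
    lo, hi = sorted((s1, s2))
    a = personalize_rates(_rates(p, p, p, 0.0), lo)
    b = personalize_rates(_rates(p, p, p, 0.0), hi)
    tol = 1e-12  # roundoff of 1−(1−p)^m at the tiniest probabilities
    assert b.normal_to_pre.value >= a.normal_to_pre.value - tol
    assert b.pre_to_stage1.value >= a.pre_to_stage1.value - tol
    assert b.stage1_to_stage2.value >= a.stage1_to_stage2.value - tol


@settings(max_examples=100, derandomize=True)
@given(p=st.floats(0, 1), m=st.floats(0, 10))
def test_scaled_probabilities_stay_valid(p, m):
    assert 0.0 <= scale_probability(p, m) <= 1.0
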
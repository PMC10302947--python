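"""Strategy encoding, efficacy mapping, compliance dilution, parameter modification."""

import dataclasses

import numpy as np
import pytest

from htncea.engine import evaluate_strategy
from htncea.interventions import (
    StrategySpec,
    apply_strategy,
    bp_reduction_to_hazard_ratio,
    default_strategies,
    effective_hazard_ratio,
    get_strategy,
)
from htncea.natural_history import GROUPS, build_transition_matrix
from htncea.parameters import COST_KEYS, Param, STATES


@pytest.mark.parametrize("dsbp, hr", [
    (0.0, 1.0),
    (20.0, 0.5),
    (7.0, 2 ** (-0.35)),
    (16.0, 2 ** (-0.8)),
    (40.0, 0.25),
])
def test_bp_reduction_hazard_ratio_log_linear(dsbp, hr):
    assert bp_reduction_to_hazard_ratio(dsbp) == pytest.approx(hr, rel=1e-12)


def test_negative_bp_reduction_rejected():
    with pytest.raises(ValueError):
        bp_reduction_to_hazard_ratio(-1.0)


@pytest.mark.parametrize("hr, c, expected", [
    (0.3, 0.0, 1.0),
    (0.3, 1.0, 0.3),
    (2 ** (-0.35), 0.6, 0.6 * 2 ** (-0.35) + 0.4),
])
def test_effective_hazard_ratio_compliance_mixture(hr, c, expected):
    assert effective_hazard_ratio(hr, c) == pytest.approx(expected, rel=1e-12)


def test_effective_hazard_ratio_numeric_example():
    # 7 mm Hg reduction at 60% compliance
    assert effective_hazard_ratio(0.7846, 0.6) == pytest.approx(0.8708, abs=5e-5)


def test_usual_care_changes_nothing_but_costs(base_ps):
    mod = apply_strategy(base_ps, get_strategy("usual_care"))
    for attr in ("normal_to_pre", "pre_to_stage1", "stage1_to_stage2", "pre_to_normal"):
        assert getattr(mod.transition, attr).value == getattr(base_ps.transition, attr).value
    assert np.array_equal(mod.intervention_cost_per_state, np.zeros(4))


def test_zero_compliance_leaves_rates_untouched_but_adds_cost(base_ps):
    ps = base_ps
    ps.compliance.lifestyle = Param(0.0)
    mod = apply_strategy(ps, get_strategy("population_wide"))
    assert mod.transition.normal_to_pre.value == ps.transition.normal_to_pre.value
    assert mod.hazards.ami.pre.value == ps.hazards.ami.pre.value
    assert mod.intervention_cost_per_state[:3].min() > 0  # programme cost remains
    assert mod.intervention_cost_per_state[3] == 0  # stage II not targeted


def test_drug_bundle_scales_on_rate_scale(base_ps):
    """HR 0.5 at 50% compliance gives p' = 1 − (1−p)^0.75 for the covered state."""
    ps = base_ps
    ps.efficacy.sbp_reduction["pre"] = 20.0  # HR 0.5
    ps.compliance.medication = Param(0.5)
    spec = StrategySpec("drug_only", {(s, g): (("drug",) if s == "pre" else ())
                                      for s in STATES for g in GROUPS})
    mod = apply_strategy(ps, spec, group="mid")
    p = ps.transition.pre_to_stage1.value
    assert mod.transition.pre_to_stage1.value == pytest.approx(1 - (1 - p) ** 0.75, rel=1e-12)
    h = ps.hazards.stroke.pre.value
    assert mod.hazards.stroke.pre.value == pytest.approx(1 - (1 - h) ** 0.75, rel=1e-12)


def test_awareness_has_no_effect_in_stage2_but_drug_does(base_ps):
    lifestyle = StrategySpec("ls", {(s, g): ("lifestyle_full",)
                                    for s in STATES for g in GROUPS})
    mod = apply_strategy(base_ps, lifestyle, "mid")
    assert mod.hazards.ami.stage2.value == base_ps.hazards.ami.stage2.value
    assert mod.hazards.ami.stage1.value < base_ps.hazards.ami.stage1.value

    drug = StrategySpec("rx", {(s, g): ("drug",) for s in STATES for g in GROUPS})
    mod = apply_strategy(base_ps, drug, "mid")
    assert mod.hazards.ami.stage2.value < base_ps.hazards.ami.stage2.value


def test_regression_rate_never_boosted(base_ps):
    for name in ("population_wide", "high_risk", "personalized"):
        for group in GROUPS:
            mod = apply_strategy(base_ps, get_strategy(name), group)
            assert mod.transition.pre_to_normal.value == base_ps.transition.pre_to_normal.value


def test_modified_rows_remain_stochastic_for_all_strategies(base_ps):
    for name, spec in default_strategies().items():
        for group in GROUPS:
            mod = apply_strategy(base_ps, spec, group)
            m = build_transition_matrix(mod.transition)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12), (name, group)
            assert np.all(m >= 0)


def test_unknown_bundle_key_raises():
    spec = StrategySpec("bogus", {("pre", "mid"): ("not_a_bundle",)})
    with pytest.raises(KeyError, match="not_a_bundle"):
        spec.bundles("pre", "mid")


def test_unknown_strategy_name_raises():
    with pytest.raises(KeyError):
        get_strategy("polypill")


def test_strategy_overrides_from_config(base_ps):
    overrides = {"population_wide": {"bundles": ["lifestyle_low"], "states": ["pre"]}}
    spec = get_strategy("population_wide", overrides)
    mod = apply_strategy(base_ps, spec)
    assert mod.intervention_cost_per_state[1] == base_ps.costs.lifestyle_low.value
    assert mod.intervention_cost_per_state[0] == 0


def test_qalys_monotone_in_compliance(base_ps):
    """Higher lifestyle compliance can only improve population QALYs."""
    qalys = []
    for c in (0.0, 0.3, 0.6, 1.0):
        ps = base_ps.copy()
        ps.compliance.lifestyle = Param(c)
        res = evaluate_strategy(ps, get_strategy("population_wide"))
        qalys.append(res.qaly)
    assert all(b >= a - 1e-12 for a, b in zip(qalys, qalys[1:]))


def test_active_strategies_weakly_dominate_usual_care_in_qalys(base_ps):
    """With positive efficacy, prevention never loses QALYs relative to usual care."""
    base = evaluate_strategy(base_ps, get_strategy("usual_care"))
    for name in ("population_wide", "high_risk", "personalized"):
        res = evaluate_strategy(base_ps, get_strategy(name))
        assert res.qaly >= base.qaly - 1e-12, name
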
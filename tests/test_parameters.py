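"""Parameter schema: distributions, config loading/validation, sampling."""

import dataclasses

import numpy as np
import pytest
import yaml

from htncea.parameters import (
    ConfigError,
    Distribution,
    Param,
    SECTION24_HAZARDS,
    default_config_path,
    distribution_mean,
    dump_parameters,
    iter_params,
    load_default_parameters,
    load_parameters,
    sample_parameter_set,
)


@pytest.mark.parametrize("dist, expected", [
    (Distribution.beta(30, 9970), 0.003),
    (Distribution.beta(15, 85), 0.15),
    (Distribution.beta(32, 9968), 0.0032),
    (Distribution.triangular(2, 2, 2), 2.0),
    (Distribution.triangular(0, 0.03, 0.05), 0.08 / 3),
    (Distribution.triangular(2706, 3006, 3068), (2706 + 3006 + 3068) / 3),
    (Distribution.point(0.42), 0.42),
])
def test_distribution_mean_closed_forms(dist, expected):
    assert distribution_mean(dist) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("ctor, args", [
    (Distribution.beta, (0, 5)),
    (Distribution.beta, (5, -1)),
    (Distribution.triangular, (1, 0.5, 2)),
    (Distribution.triangular, (0, 2, 1)),
])
def test_invalid_distribution_parameters_rejected(ctor, args):
    with pytest.raises(ConfigError):
        ctor(*args)


def test_bundled_config_base_case_values(base_ps):
    ps = base_ps
    assert ps.discount_rate.value == 0.03
    assert ps.horizon_years == 20
    assert ps.compliance.lifestyle.value == 0.60
    assert ps.compliance.screening.value == 0.70
    assert ps.compliance.medication.value == 0.50
    assert ps.hazards.ami.normal.value == 0.003
    assert ps.hazards.ami.stage2.value == 0.008737
    assert ps.hazards.stroke.stage1.value == 0.001675
    assert ps.hazards.esrd.mortality_yearly.value == 0.30
    assert ps.efficacy.sbp_reduction == {"normal": 7.0, "pre": 7.0,
                                         "stage1": 16.0, "stage2": 19.5}
    assert ps.initial_state_distribution.sum() == pytest.approx(1.0)


def test_section24_preset_overrides_narrative_hazards():
    ps = load_default_parameters(preset="section24")
    for comp, states in SECTION24_HAZARDS.items():
        for state, value in states.items():
            assert getattr(ps.hazards[comp], state).value == value
    # normal-state hazards keep their tabulated values
    assert ps.hazards.ami.normal.value == 0.003
    # distributions are untouched by the preset
    assert ps.hazards.ami.pre.dist.kind == "beta"


def _raw_config():
    with open(default_config_path()) as fh:
        return yaml.safe_load(fh)


def _load_raw(tmp_path, raw):
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(raw))
    return load_parameters(path)


def test_out_of_range_probability_names_the_key(tmp_path):
    raw = _raw_config()
    raw["transition"]["pre_to_normal"] = 1.2
    with pytest.raises(ConfigError, match="pre_to_normal"):
        _load_raw(tmp_path, raw)


def test_missing_block_is_reported_by_name(tmp_path):
    raw = _raw_config()
    del raw["utilities"]
    with pytest.raises(ConfigError, match="utilities"):
        _load_raw(tmp_path, raw)


def test_missing_nested_key_is_reported_with_path(tmp_path):
    raw = _raw_config()
    del raw["hazards"]["stroke"]["mortality_yearly"]
    with pytest.raises(ConfigError, match="hazards.stroke.mortality_yearly"):
        _load_raw(tmp_path, raw)


def test_pre_row_exit_sum_above_one_rejected(tmp_path):
    raw = _raw_config()
    raw["transition"]["pre_to_stage1"] = 0.6
    raw["transition"]["pre_to_normal"] = 0.6
    with pytest.raises(ConfigError, match="pre_to_stage1 \\+ pre_to_normal"):
        _load_raw(tmp_path, raw)


def test_nonexistent_config_file_rejected(tmp_path):
    with pytest.raises(ConfigError, match="not found"):
        load_parameters(tmp_path / "missing.yaml")


def test_sampling_is_deterministic_under_fixed_seed(base_ps):
    a = sample_parameter_set(base_ps, 1)
    b = sample_parameter_set(base_ps, 1)
    assert [p.value for _, p in iter_params(a)] == [p.value for _, p in iter_params(b)]
    c = sample_parameter_set(base_ps, 2)
    assert [p.value for _, p in iter_params(a)] != [p.value for _, p in iter_params(c)]


def test_sampling_point_distributions_is_identity(point_ps):
    sampled = sample_parameter_set(point_ps, 123)
    for (path, orig), (_, new) in zip(iter_params(point_ps), iter_params(sampled)):
        assert new.value == orig.value, path


def test_sampled_sets_satisfy_all_invariants(base_ps):
    from htncea.parameters import validate_parameter_set

    for seed in range(25):
        sampled = sample_parameter_set(base_ps, seed)
        validate_parameter_set(sampled, base_case=False)
        tr = sampled.transition
        assert tr.pre_to_stage1.value + tr.pre_to_normal.value <= 1.0 + 1e-12


def test_overflowing_multinomial_row_is_renormalised_with_warning(base_ps):
    ps = base_ps
    ps.transition.pre_to_stage1 = Param(0.6, Distribution.beta(60, 40))
    ps.transition.pre_to_normal = Param(0.6, Distribution.beta(60, 40))
    saw_warning = False
    for seed in range(40):
        import warnings

        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            sampled = sample_parameter_set(ps, seed)
        tr = sampled.transition
        assert tr.pre_to_stage1.value + tr.pre_to_normal.value <= 1.0 + 1e-12
        saw_warning |= any("renormalising" in str(w.message) for w in rec)
    assert saw_warning


@pytest.mark.parametrize("dist, n", [
    (Distribution.beta(30, 9970), 100_000),
    (Distribution.beta(50, 50), 50_000),
    (Distribution.triangular(2000, 5000, 10000), 50_000),
])
def test_empirical_mean_converges_to_closed_form(dist, n):
    """Monte-Carlo mean matches the analytic mean within 4 standard errors."""
    rng = np.random.Generator(np.random.Philox(2024))
    draws = np.array([dist.sample(rng) for _ in range(n)])
    if dist.kind == "beta":
        a, b = dist.params
        var = a * b / ((a + b) ** 2 * (a + b + 1))
    else:
        low, mode, high = dist.params
        var = (low**2 + mode**2 + high**2 - low * mode - low * high - mode * high) / 18
    se = np.sqrt(var / n)
    assert abs(draws.mean() - dist.mean()) < 4 * se


def test_config_round_trips_point_values_bit_identically(base_ps, tmp_path):
    path = tmp_path / "roundtrip.yaml"
    dump_parameters(base_ps, path)
    again = load_parameters(path)
    for (key, orig), (_, new) in zip(iter_params(base_ps), iter_params(again)):
        assert new.value == orig.value, key
        assert new.dist == orig.dist, key
    assert again.horizon_years == base_ps.horizon_years
    assert np.array_equal(again.initial_state_distribution,
                          base_ps.initial_state_distribution)
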
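import dataclasses

import pytest

from htncea.parameters import (
    Distribution,
    Param,
    load_default_parameters,
    iter_params,
)

_BASE = load_default_parameters()


@pytest.fixture
def base_ps():
    """Fresh copy of the bundled base-case parameter set."""
    return _BASE.copy()


def make_point(ps):
    """Collapse every uncertainty distribution to a point mass at its base value."""
    out = ps.copy()
    from htncea.parameters import _set_by_path  # test helper use of the walker

    for path, param in list(iter_params(out)):
        _set_by_path(out, path, dataclasses.replace(
            param, dist=Distribution.point(param.value)))
    return out


@pytest.fixture
def point_ps(base_ps):
    """Base-case parameters with all uncertainty removed (degenerate PSA)."""
    return make_point(base_ps)


@pytest.fixture
def risk_groups(base_ps):
    from htncea.synthetic import SyntheticCohortSpec, generate_profiles, make_risk_groups

    spec = SyntheticCohortSpec.from_risk_model(base_ps.risk, n=2000, seed=11)
    _, groups = make_risk_groups(generate_profiles(spec))
    return groups
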
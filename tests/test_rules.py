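"""Unit and property tests for the per-trial weight-update rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microzone import (
    ConfigurationError,
    DispatchError,
    RuleParams,
    apply_trial,
    step_adjusted_extinction,
    step_core,
    step_inertia,
)

WEIGHTS = st.floats(min_value=1e-6, max_value=1 - 1e-6)


@pytest.mark.parametrize(
    "fn, L, T, params, expected",
    [
        (step_core, 0.75, 1, RuleParams(k=0.5), 0.875),
        (step_core, 0.3, 1, RuleParams(k=0.1), 0.37),
        (step_inertia, 0.5, 1, RuleParams(k=0.1), 0.525),
        (step_inertia, 0.5, 0, RuleParams(k=0.1), 0.475),
    ],
)
def test_step_hand_computed_examples(fn, L, T, params, expected):
    assert fn(L, T, params) == pytest.approx(expected, abs=1e-12)


def test_adjusted_extinction_hand_computed():
    # 0.9 - 0.9 * 0.1^2 / (0.5 * 0.9) = 0.88
    params = RuleParams(k=0.1, b=0.5, variant="inertia_adjusted")
    assert step_adjusted_extinction(0.9, params) == pytest.approx(0.88, abs=1e-12)


@pytest.mark.parametrize("L0", [0.001, 0.01, 0.3])
@pytest.mark.parametrize("k", [0.05, 0.1, 0.15])  # (1-k)^100 above the clamp
def test_core_all_paired_matches_geometric_closed_form(L0, k):
    """Unrolling the core recurrence gives L_n = 1 - (1-L0)(1-k)^n."""
    params = RuleParams(k=k, variant="core")
    L = L0
    for n in range(1, 101):
        L = step_core(L, 1, params)
        assert L == pytest.approx(1 - (1 - L0) * (1 - k) ** n, abs=1e-12)


@pytest.mark.parametrize("L", [0.1, 0.25, 0.5, 0.7, 0.93])
def test_inertia_up_down_symmetry(L, inertia_params):
    """|step| for (L, paired) equals |step| for (1-L, unpaired)."""
    up = step_inertia(L, 1, inertia_params) - L
    down = (1 - L) - step_inertia(1 - L, 0, inertia_params)
    assert up == pytest.approx(down, abs=1e-12)


def test_inertia_boundaries_are_near_fixed_points(inertia_params):
    eps = inertia_params.eps
    # at the floor a paired trial barely moves the weight (and vice versa)
    assert step_inertia(eps, 1, inertia_params) - eps <= 2 * inertia_params.k * eps
    assert (1 - eps) - step_inertia(1 - eps, 0, inertia_params) <= 2 * inertia_params.k * eps


def test_sigmoid_acquisition_shape(inertia_params):
    """All-paired inertia trajectory is S-shaped: increments rise then fall."""
    L = 0.01
    traj = [L]
    for _ in range(200):
        L = step_inertia(L, 1, inertia_params)
        traj.append(L)
    inc = np.diff(traj)
    assert inc.max() == pytest.approx(
        inertia_params.k * 0.25, rel=0.05
    )  # maximal increment near L = 0.5
    sign_changes = np.sum(np.diff(np.sign(np.diff(inc))) != 0)
    assert sign_changes == 1


class TestAdjustedExtinction:
    def test_dispatch_error_at_or_below_threshold(self, adjusted_params):
        with pytest.raises(DispatchError):
            step_adjusted_extinction(0.4, adjusted_params)
        with pytest.raises(DispatchError):
            step_adjusted_extinction(0.5, adjusted_params)

    def test_step_vanishes_towards_saturation(self, adjusted_params):
        grid = np.linspace(0.51, 1 - 1e-9, 200)
        steps = grid - np.array(
            [step_adjusted_extinction(L, adjusted_params) for L in grid]
        )
        assert np.all(np.diff(steps) < 0)  # strictly decreasing in L
        assert steps[-1] < 1e-8

    @pytest.mark.parametrize("k", [0.05, 0.1, 0.3, 0.5])
    def test_no_overshoot_when_b_at_least_k(self, k):
        """Brute-force grid: the down step never drives the weight to 0."""
        b = max(0.5, k)
        params = RuleParams(k=k, b=b, variant="inertia_adjusted")
        grid = np.linspace(b + 1e-6, 1 - 1e-9, 2000)
        out = np.array([step_adjusted_extinction(L, params) for L in grid])
        assert np.all(out > 0)

    def test_smaller_than_plain_step_near_saturation(self, adjusted_params):
        for L in np.linspace(0.96, 1 - 1e-6, 50):
            adj = L - step_adjusted_extinction(L, adjusted_params)
            plain = L - step_inertia(L, 0, adjusted_params)
            assert adj < plain


class TestApplyTrial:
    def test_inactive_identity(self, adjusted_params):
        for L in (0.001, 0.5, 0.97):
            assert apply_trial(L, 1, False, adjusted_params) == L

    def test_routing_below_threshold_uses_inertia(self, adjusted_params):
        assert apply_trial(0.4, 0, True, adjusted_params) == step_inertia(
            0.4, 0, adjusted_params
        )

    def test_routing_above_threshold_uses_adjusted(self, adjusted_params):
        assert apply_trial(0.9, 0, True, adjusted_params) == pytest.approx(
            0.88, abs=1e-12
        )

    def test_vectorised_mixed_routing(self, adjusted_params):
        L = np.array([0.4, 0.9, 0.7])
        active = np.array([True, True, False])
        out = apply_trial(L, 0, active, adjusted_params)
        assert out[0] == step_inertia(0.4, 0, adjusted_params)
        assert out[1] == pytest.approx(0.88, abs=1e-12)
        assert out[2] == 0.7  # inactive untouched


@pytest.mark.parametrize(
    "kwargs",
    [
        {"k": 0.0},
        {"k": 1.0},
        {"b": 0.0},
        {"b": 1.0},
        {"variant": "perceptron"},
        {"k": 0.6, "b": 0.5, "variant": "inertia_adjusted"},  # b < k
        {"eps": 0.0},
        {"eps": 0.6},
        {"inertia_strength": 0.0},
    ],
)
def test_parameter_validation(kwargs):
    with pytest.raises(ConfigurationError):
        RuleParams(**kwargs)


def test_weight_domain_checked(inertia_params):
    with pytest.raises(ConfigurationError):
        step_core(0.0, 1, inertia_params)
    with pytest.raises(ConfigurationError):
        step_inertia(1.0, 0, inertia_params)
    with pytest.raises(ConfigurationError):
        step_core(0.5, 2, inertia_params)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    L0=WEIGHTS,
    k=st.floats(min_value=0.01, max_value=0.99),
    variant=st.sampled_from(["core", "inertia", "inertia_adjusted"]),
    teachers=st.lists(st.integers(min_value=0, max_value=1), min_size=1, max_size=300),
)
def test_weights_remain_strictly_bounded(L0, k, variant, teachers):
    """No teaching-signal sequence can push a weight out of [eps, 1-eps]."""
    b = max(0.5, k)
    params = RuleParams(k=k, b=b, variant=variant)
    L = L0
    for T in teachers:
        L = apply_trial(L, T, True, params)
        assert params.eps <= L <= 1 - params.eps


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    L0=st.floats(min_value=0.001, max_value=0.5),
    variant=st.sampled_from(["core", "inertia", "inertia_adjusted"]),
)
def test_all_paired_monotone_all_unpaired_monotone(L0, variant):
    params = RuleParams(k=0.1, variant=variant)
    L = L0
    for _ in range(100):
        nxt = apply_trial(L, 1, True, params)
        assert nxt >= L
        L = nxt
    L = 1 - L0
    for _ in range(100):
        nxt = apply_trial(L, 0, True, params)
        assert nxt <= L
        L = nxt
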
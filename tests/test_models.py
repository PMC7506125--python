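"""Unit and property tests for the value-update and choice rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surpriserl.models import (
    AgentState,
    ModelParams,
    choice_probabilities,
    decayed_learning_rate,
    surprise_utility,
    update_state,
    utility_transform,
)

finite_rewards = st.floats(min_value=-50, max_value=50, allow_nan=False)


@pytest.mark.parametrize(
    "alpha, t_s, clip, expected",
    [
        (0.2, 0, False, 0.7),
        (0.5, 9, False, 0.55),
        (0.8, 0, True, 1.0),
        (0.0, 0, False, 0.5),
        (1.0, 999_999, False, pytest.approx(1.0, abs=1e-5)),
    ],
)
def test_decayed_learning_rate_values(alpha, t_s, clip, expected):
    assert decayed_learning_rate(alpha, t_s, clip) == pytest.approx(expected)


def test_decayed_learning_rate_monotone_in_exposure():
    rates = [decayed_learning_rate(0.3, t) for t in range(20)]
    assert all(a > b for a, b in zip(rates, rates[1:]))
    assert rates[-1] > 0.3


@pytest.mark.parametrize("alpha, t_s", [(-0.1, 0), (1.1, 0), (0.5, -1)])
def test_decayed_learning_rate_domain_errors(alpha, t_s):
    with pytest.raises(ValueError):
        decayed_learning_rate(alpha, t_s)


@pytest.mark.parametrize(
    "r, q, d, expected",
    [(40, 20, 0.5, 30), (7, 7, 0.9, 7), (0, 20, 1, -20), (10, 10, 0, 10)],
)
def test_surprise_utility_values(r, q, d, expected):
    assert surprise_utility(r, q, d) == expected


@given(r=finite_rewards, q=finite_rewards, d=st.floats(min_value=0, max_value=1))
@settings(max_examples=100, derandomize=True)
def test_surprise_never_exceeds_outcome_for_positive_d(r, q, d):
    assert surprise_utility(r, q, d) <= r
    assert surprise_utility(r, q, 0.0) == r


def test_surprise_utility_rejects_bad_inputs():
    with pytest.raises(ValueError):
        surprise_utility(float("nan"), 0.0, 0.5)
    with pytest.raises(ValueError):
        surprise_utility(1.0, 0.0, 1.5)


def test_utility_transform_anchors():
    assert utility_transform(0, 5) == 0
    assert utility_transform(20, 5) == 20
    assert utility_transform(40, 5) == 100
    assert utility_transform(40, 2) == 40  # a=2 is the identity on the support


def test_utility_transform_continuous_extension_matches_anchors():
    for a in (1.0, 2.0, 7.5, 30.0):
        for r in (0.0, 20.0, 40.0):
            assert utility_transform(r, a, continuous=True) == pytest.approx(
                utility_transform(r, a)
            )
    # scaled units keep the anchor structure
    assert utility_transform(2.0, 3.0, continuous=True, unit=1.0) == pytest.approx(3.0)


def test_utility_transform_discrete_domain_error():
    with pytest.raises(ValueError):
        utility_transform(10.0, 5.0)
    with pytest.raises(ValueError):
        utility_transform(20.0, 0.5)


class TestChoiceProbabilities:
    def test_softmax_worked_example(self):
        state = AgentState(Q={"a": 1.0, "b": 0.0}, T={"a": 0, "b": 0})
        p = choice_probabilities(state, ModelParams("qlearning", alpha=0.5, beta=2.0), ("a", "b"))
        assert p == pytest.approx([0.8808, 0.1192], abs=5e-5)

    def test_zero_temperature_is_uniform(self):
        state = AgentState(Q={"a": 5.0, "b": -3.0}, T={"a": 0, "b": 0})
        p = choice_probabilities(state, ModelParams("qlearning", alpha=0.5, beta=0.0), ("a", "b"))
        assert p == pytest.approx([0.5, 0.5])

    def test_equal_values_give_one_over_k(self):
        state = AgentState(Q={s: 2.5 for s in "abcd"}, T={s: 0 for s in "abcd"})
        p = choice_probabilities(state, ModelParams("qlearning", alpha=0.5, beta=7.0), tuple("abcd"))
        assert p == pytest.approx([0.25] * 4)

    def test_empty_offer_rejected(self):
        state = AgentState(Q={"a": 0.0}, T={"a": 0})
        with pytest.raises(ValueError):
            choice_probabilities(state, ModelParams("qlearning", alpha=0.5, beta=1.0), ())

    # |beta * (Q_i - Q_j)| stays below ~700 so exp() cannot underflow to
    # exactly zero; strict positivity holds analytically for any finite gap
    @given(
        qs=st.lists(st.floats(min_value=-35, max_value=35), min_size=2, max_size=5),
        beta=st.floats(min_value=0, max_value=10),
        shift=st.floats(min_value=-500, max_value=500),
    )
    @settings(max_examples=100, derandomize=True)
    def test_simplex_and_shift_invariance(self, qs, beta, shift):
        ids = [f"s{i}" for i in range(len(qs))]
        params = ModelParams("qlearning", alpha=0.5, beta=beta)
        state = AgentState(Q=dict(zip(ids, qs)), T={i: 0 for i in ids})
        p = choice_probabilities(state, params, tuple(ids))
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0) and np.all(p < 1 + 1e-12)
        shifted = AgentState(Q={i: q + shift for i, q in zip(ids, qs)}, T={i: 0 for i in ids})
        p2 = choice_probabilities(shifted, params, tuple(ids))
        assert p2 == pytest.approx(p, abs=1e-9)


class TestUpdateState:
    def _state(self, q=0.0):
        return AgentState(Q={"a": q, "b": 1.0}, T={"a": 0, "b": 0})

    def test_qlearning_half_step_without_decay(self):
        state = update_state(
            self._state(), ModelParams("qlearning", alpha=0.5, beta=1.0), "a", 1.0, decay=False
        )
        assert state.Q["a"] == 0.5
        assert state.T["a"] == 1

    def test_unchosen_stimuli_untouched(self):
        before = self._state()
        after = update_state(before, ModelParams("qlearning", alpha=0.5, beta=1.0), "a", 3.0)
        assert after.Q["b"] == before.Q["b"] == 1.0
        assert after.T["b"] == 0

    def test_risk_sensitive_zero_error_leaves_value(self):
        params = ModelParams("risk_sensitive", alpha_pos=0.9, alpha_neg=0.1, beta=1.0)
        state = update_state(self._state(q=2.0), params, "a", 2.0)
        assert state.Q["a"] == 2.0
        assert state.T["a"] == 1

    def test_risk_sensitive_uses_asymmetric_rates(self):
        params = ModelParams("risk_sensitive", alpha_pos=0.8, alpha_neg=0.2, beta=1.0)
        up = update_state(self._state(q=1.0), params, "a", 2.0, decay=False)
        down = update_state(self._state(q=1.0), params, "a", 0.0, decay=False)
        assert up.Q["a"] == pytest.approx(1.0 + 0.8 * 1.0)
        assert down.Q["a"] == pytest.approx(1.0 - 0.2 * 1.0)

    def test_unknown_stimulus_raises_key_error(self):
        with pytest.raises(KeyError):
            update_state(self._state(), ModelParams("qlearning", alpha=0.5, beta=1.0), "zzz", 1.0)


@given(
    rewards=st.lists(st.sampled_from([0.0, 20.0, 40.0]), min_size=1, max_size=40),
    alpha=st.floats(min_value=0, max_value=1),
)
@settings(max_examples=60, derandomize=True)
def test_nested_models_share_trajectories(rewards, alpha):
    """surprise(d=0), risk_sensitive(a+=a-) and utility(a=2) all collapse to Q-learning."""
    variants = [
        ModelParams("qlearning", alpha=alpha, beta=1.0),
        ModelParams("surprise", alpha=alpha, beta=1.0, d=0.0),
        ModelParams("risk_sensitive", alpha_pos=alpha, alpha_neg=alpha, beta=1.0),
        ModelParams("utility", alpha=alpha, beta=1.0, a=2.0),
    ]
    states = [AgentState(Q={"a": 0.0}, T={"a": 0}) for _ in variants]
    for r in rewards:
        states = [update_state(s, p, "a", r) for s, p in zip(states, variants)]
        values = {s.Q["a"] for s in states}
        assert len(values) == 1  # bit-identical across the nested variants


def test_model_params_validation_and_round_trip():
    p = ModelParams("surprise", alpha=0.3, beta=2.0, d=0.5)
    assert ModelParams.from_dict(p.to_dict()) == p
    assert p.free_names == ("alpha", "beta", "d")
    v = p.to_vector()
    assert ModelParams.from_vector("surprise", v) == p
    with pytest.raises(ValueError):
        ModelParams("surprise", alpha=0.3, beta=2.0)  # d missing
    with pytest.raises(ValueError):
        ModelParams("qlearning", alpha=1.2, beta=2.0)  # outside box
    with pytest.raises(ValueError):
        ModelParams("not_a_model", alpha=0.5, beta=1.0)
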
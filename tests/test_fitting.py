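"""Tests for likelihood replay, MAP estimation, and Laplace evidence."""

import math

import numpy as np
import pytest

from surpriserl.fitting import (
    default_priors,
    laplace_log_evidence,
    log_posterior,
    map_fit,
    session_log_likelihood,
)
from surpriserl.models import AgentState, ModelParams, choice_probabilities, update_state
from surpriserl.simulate import SessionData, TrialRecord, simulate_agent
from surpriserl.tasks import TaskSpec, build_bernoulli_bandit


def _empty_session(task):
    return SessionData("empty", TaskSpec(stimuli=task.stimuli, trials=()), [])


def test_zero_beta_likelihood_counts_choice_trials(bandit_task):
    records = [
        TrialRecord(i, "choice", ("arm1", "arm2"), "arm1", 1.0) for i in range(1, 11)
    ]
    sess = SessionData("s", bandit_task, records)
    params = ModelParams("qlearning", alpha=0.5, beta=0.0)
    assert session_log_likelihood(params, sess) == pytest.approx(10 * math.log(0.5))


def test_forced_trials_contribute_no_likelihood(risk_task_cents):
    forced = [t for t in risk_task_cents.trials if t.trial_type == "forced"]
    records = [
        TrialRecord(i, "forced", t.offered, t.offered[0], 20.0 if t.offered[0] == "sure20" else 0.0)
        for i, t in enumerate(forced, 1)
    ]
    sess = SessionData("s", risk_task_cents, records)
    params = ModelParams("qlearning", alpha=0.5, beta=2.0)
    assert session_log_likelihood(params, sess) == 0.0


def test_single_choice_softmax_term(bandit_task):
    # one choice trial with pre-trial values (1, 0) at beta=2: log(0.8808)
    records = [
        TrialRecord(1, "forced", ("arm1",), "arm1", 1.0),  # drives Q(arm1) to 1
        TrialRecord(2, "choice", ("arm1", "arm2"), "arm1", 1.0),
    ]
    sess = SessionData("s", bandit_task, records)
    params = ModelParams("qlearning", alpha=1.0, beta=2.0)
    ll = session_log_likelihood(params, sess, decay=False)
    assert ll == pytest.approx(math.log(1.0 / (1.0 + math.exp(-2.0))), abs=1e-9)


def test_likelihood_replay_is_pure(surprise_risk_session):
    params = ModelParams("surprise", alpha=0.5, beta=2.0, d=0.4)
    first = session_log_likelihood(params, surprise_risk_session)
    second = session_log_likelihood(params, surprise_risk_session)
    assert first == second  # bit-identical


@pytest.mark.parametrize(
    "params",
    [
        ModelParams("qlearning", alpha=0.3, beta=1.5),
        ModelParams("surprise", alpha=0.6, beta=2.0, d=0.7),
        ModelParams("risk_sensitive", alpha_pos=0.7, alpha_neg=0.2, beta=1.0),
        ModelParams("utility", alpha=0.4, beta=0.2, a=4.0),
    ],
)
def test_fast_replay_matches_state_machine(params, surprise_risk_session):
    """The vectorized likelihood equals a naive replay via the public update rules."""
    sess = surprise_risk_session
    state = AgentState.initial(sess.task.stimulus_ids)
    unit = 20.0 * sess.task.reward_scale
    ll = 0.0
    for t in sess.trials:
        if t.trial_type == "choice":
            probs = choice_probabilities(state, params, t.offered)
            ll += math.log(probs[t.offered.index(t.choice)])
        state = update_state(state, params, t.choice, t.reward, utility_unit=unit)
    assert session_log_likelihood(params, sess) == pytest.approx(ll, abs=1e-10)


class TestLogPosterior:
    def test_flat_prior_contributes_its_log_density(self, bandit_task, priors):
        sess = _empty_session(bandit_task)
        ql = log_posterior(ModelParams("qlearning", alpha=0.5, beta=3.0), sess, priors)
        sp = log_posterior(ModelParams("surprise", alpha=0.5, beta=3.0, d=0.3), sess, priors)
        assert sp - ql == pytest.approx(math.log(0.5))  # Uniform(-1,1) density

    def test_outside_support_is_minus_infinity(self, bandit_task, priors):
        sess = _empty_session(bandit_task)
        lp = log_posterior(ModelParams("qlearning", alpha=0.5, beta=0.0), sess, priors)
        assert lp == -math.inf  # Gamma(2, 3) density vanishes at beta=0

    def test_extra_choice_trial_never_raises_posterior(self, bandit_task, priors):
        params = ModelParams("qlearning", alpha=0.5, beta=2.0)
        records = [
            TrialRecord(i, "choice", ("arm1", "arm2"), "arm1", 1.0) for i in range(1, 6)
        ]
        short = SessionData("s", bandit_task, records[:-1])
        full = SessionData("s", bandit_task, records)
        assert log_posterior(params, full, priors) <= log_posterior(params, short, priors)


class TestMapFit:
    def test_recovers_generating_parameters_at_large_n(self):
        task = build_bernoulli_bandit((0.8, 0.2), (1.0, 1.0), 1000)
        truth = ModelParams("qlearning", alpha=0.3, beta=2.0)
        sess = simulate_agent(truth, task, seed=21)
        fit = map_fit("qlearning", sess, n_restarts=5, seed=0)
        assert fit.converged
        assert abs(fit.params_hat.alpha - 0.3) < 0.1
        assert abs(fit.params_hat.beta - 2.0) < 0.5

    def test_surprise_fit_to_qlearning_data_finds_null_d(self):
        task = build_bernoulli_bandit((0.8, 0.2), (1.0, 1.0), 1000)
        sess = simulate_agent(ModelParams("qlearning", alpha=0.3, beta=2.0), task, seed=22)
        fit = map_fit("surprise", sess, n_restarts=5, seed=0)
        assert abs(fit.params_hat.d) < 0.15

    def test_deterministic_given_seed(self, ql_bandit_session):
        a = map_fit("qlearning", ql_bandit_session, n_restarts=3, seed=5)
        b = map_fit("qlearning", ql_bandit_session, n_restarts=3, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_empty_session_returns_prior_modes(self, bandit_task):
        sess = _empty_session(bandit_task)
        fit = map_fit("qlearning", sess, n_restarts=5, seed=1)
        assert fit.params_hat.alpha == pytest.approx(0.5, abs=1e-3)  # Beta(2,2) mode
        assert fit.params_hat.beta == pytest.approx(3.0, abs=1e-3)  # Gamma(2, scale 3) mode

    def test_invalid_arguments(self, ql_bandit_session):
        with pytest.raises(ValueError):
            map_fit("qlearning", ql_bandit_session, n_restarts=0)
        with pytest.raises(ValueError):
            map_fit("nope", ql_bandit_session)


class TestLaplace:
    def test_gaussian_log_posterior_is_exact(self):
        m, s, c = 0.4, 0.07, -12.3
        res = laplace_log_evidence(lambda th: (th[0] - m) ** 2 / (2 * s * s) - c, np.array([m]))
        assert res.log_evidence == pytest.approx(c + 0.5 * math.log(2 * math.pi * s * s), abs=1e-6)
        assert not res.regularized

    def test_two_dimensional_gaussian(self):
        s1, s2, c = 0.2, 1.5, 3.0
        f = lambda th: th[0] ** 2 / (2 * s1 * s1) + th[1] ** 2 / (2 * s2 * s2) - c
        res = laplace_log_evidence(f, np.zeros(2))
        expected = c + math.log(2 * math.pi) + 0.5 * math.log(s1 * s1 * s2 * s2)
        assert res.log_evidence == pytest.approx(expected, abs=1e-6)

    def test_non_positive_definite_hessian_is_flagged(self):
        res = laplace_log_evidence(lambda th: -(th[0] ** 2), np.array([0.0]))
        assert res.regularized
        assert math.isfinite(res.log_evidence)


def test_complexity_penalty_on_nested_models():
    """On Q-learning data, extra parameters should not buy evidence on average."""
    task = build_bernoulli_bandit((0.8, 0.2), (1.0, 1.0), 200)
    rng_seeds = range(30)
    deltas = []
    for s in rng_seeds:
        sess = simulate_agent(ModelParams("qlearning", alpha=0.4, beta=2.0), task, seed=1000 + s)
        ql = map_fit("qlearning", sess, n_restarts=3, seed=s)
        sp = map_fit("surprise", sess, n_restarts=3, seed=s)
        deltas.append(ql.log_evidence - sp.log_evidence)
    mean = np.mean(deltas)
    sem = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
    assert mean > -2 * sem
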
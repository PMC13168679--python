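"""Q-learning agent: softmax, value updates, and session simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rewprop.agents import (
    AgentParams,
    BehavioralSession,
    compute_rpe,
    q_update,
    sample_agent_params,
    simulate_cohort,
    simulate_session,
    softmax_probs,
)
from rewprop.task import TaskConfig


class TestSoftmax:
    def test_equal_values_split_evenly(self):
        np.testing.assert_allclose(
            softmax_probs(np.array([0.5, 0.5]), beta=3.7), [0.5, 0.5]
        )

    def test_small_beta_approaches_uniform(self):
        p = softmax_probs(np.array([1.0, 0.0]), beta=1e-9, convention="gain")
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-8)

    def test_gain_convention_closed_form(self):
        # exp(5) / (exp(5) + 1) = 0.993307...
        p = softmax_probs(np.array([1.0, 0.0]), beta=5.0, convention="gain")
        expected = math.exp(5) / (math.exp(5) + 1)
        assert p[0] == pytest.approx(expected, abs=1e-9)
        assert p[0] == pytest.approx(0.99331, abs=1e-5)

    def test_temperature_is_reciprocal_of_gain(self):
        q = np.array([0.8, 0.2])
        np.testing.assert_allclose(
            softmax_probs(q, beta=5.0, convention="gain"),
            softmax_probs(q, beta=0.2, convention="temperature"),
        )

    @given(
        q=st.lists(st.floats(-5, 5), min_size=2, max_size=4),
        shift=st.floats(-10, 10),
        beta=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance_and_normalization(self, q, shift, beta):
        q = np.asarray(q)
        p = softmax_probs(q, beta)
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()
        np.testing.assert_allclose(p, softmax_probs(q + shift, beta), atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            softmax_probs(np.array([np.nan, 0.0]), beta=1.0)
        with pytest.raises(ValueError):
            softmax_probs(np.array([1.0, 0.0]), beta=0.0)
        with pytest.raises(ValueError):
            softmax_probs(np.array([1.0, 0.0]), beta=1.0, convention="bogus")


@pytest.mark.parametrize(
    "reward,q,expected", [(1, 0.0, 1.0), (0, 0.8, -0.8), (1, 0.34, 0.66)]
)
def test_rpe_is_reward_minus_expectation(reward, q, expected):
    assert compute_rpe(reward, q) == pytest.approx(expected)


class TestQUpdate:
    def test_gain_update_hand_computed(self):
        params = AgentParams(alpha_gain=0.34, alpha_loss=0.1)
        assert q_update(0.5, compute_rpe(1, 0.5), params) == pytest.approx(0.67)

    def test_zero_rates_freeze_values(self):
        params = AgentParams(alpha_gain=0.0, alpha_loss=0.0)
        assert q_update(0.5, 0.5, params) == 0.5
        assert q_update(0.5, -0.5, params) == 0.5

    def test_full_gain_step_reaches_reward(self):
        params = AgentParams(alpha_gain=1.0)
        assert q_update(0.5, compute_rpe(1, 0.5), params) == pytest.approx(1.0)

    def test_loss_rate_applies_to_negative_rpe(self):
        params = AgentParams(alpha_gain=0.9, alpha_loss=0.2)
        assert q_update(0.5, compute_rpe(0, 0.5), params) == pytest.approx(0.4)

    def test_zero_alpha_loss_ignores_losses(self):
        # a run of only Incorrect feedback leaves Q untouched
        params = AgentParams(alpha_gain=0.5, alpha_loss=0.0)
        q = 0.7
        for _ in range(10):
            q = q_update(q, compute_rpe(0, q), params)
        assert q == 0.7

    @given(
        q=st.floats(0, 1),
        reward=st.sampled_from([0.0, 1.0]),
        ag=st.floats(0, 1),
        al=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_values_stay_in_unit_interval(self, q, reward, ag, al):
        params = AgentParams(alpha_gain=ag, alpha_loss=al)
        q2 = q_update(q, compute_rpe(reward, q), params)
        assert 0.0 <= q2 <= 1.0


def test_agent_params_validation():
    with pytest.raises(ValueError):
        AgentParams(alpha_gain=1.5)
    with pytest.raises(ValueError):
        AgentParams(beta=-1.0)
    with pytest.raises(ValueError):
        AgentParams(softmax_convention="boltzmann")


class TestSimulateSession:
    def test_zero_learning_agent_is_a_coin_flipper(self, zero_learning_session):
        s = zero_learning_session
        np.testing.assert_allclose(s.choice_prob, 0.5)
        np.testing.assert_allclose(s.q_opt, 0.5)
        np.testing.assert_allclose(s.q_sub, 0.5)

    def test_same_seed_reproduces_session(self, default_config):
        p = AgentParams()
        a = simulate_session(p, default_config, seed=11)
        b = simulate_session(p, default_config, seed=11)
        assert a.trials.equals(b.trials)
        np.testing.assert_array_equal(a.rpe, b.rpe)
        np.testing.assert_array_equal(a.rt_ms, b.rt_ms)

    def test_session_layout(self, default_session, default_config):
        s = default_session
        assert s.n_training_trials == 240
        assert len(s.test) == 24
        assert (s.training["feedback"] != "none").all()
        assert (s.test["feedback"] == "none").all()
        assert set(s.training["half"]) == {"H1", "H2"}
        # RPE defined on training trials only
        assert np.isfinite(s.rpe[s.training_mask()]).all()
        assert np.isnan(s.rpe[~s.training_mask()]).all()

    def test_rpe_identity_on_chosen_value(self, default_session):
        s = default_session
        train = s.training
        tm = s.training_mask()
        opt = train["pair"].str[0]  # first pair member is optimal
        chose_opt = (train["choice"] == opt).to_numpy()
        q_chosen = np.where(chose_opt, s.q_opt[tm], s.q_sub[tm])
        reward = (train["feedback"] == "Correct").to_numpy().astype(float)
        np.testing.assert_allclose(s.rpe[tm], reward - q_chosen, atol=1e-12)

    def test_fast_learner_improves_across_halves(self):
        # expectation over replicates: second-half accuracy exceeds first
        cfg = TaskConfig()
        p = AgentParams(alpha_gain=0.9, alpha_loss=0.1, beta=15.0)
        h1 = h2 = 0.0
        n = 200
        for seed in range(n):
            s = simulate_session(p, cfg, seed=seed)
            tr = s.training
            correct = (tr["choice"] == tr["pair"].str[0]).to_numpy()
            half1 = (tr["half"] == "H1").to_numpy()
            h1 += correct[half1].mean()
            h2 += correct[~half1].mean()
        assert h2 / n > h1 / n

    def test_accuracy_increases_with_gain_rate(self):
        # monotone across an alpha_gain grid at fixed beta, within the
        # gradual-learning regime (very high rates overshoot on the
        # suboptimal stimulus and the relation becomes an inverted U)
        cfg = TaskConfig()
        grid = [0.01, 0.03, 0.08, 0.2]
        means = []
        for ag in grid:
            p = AgentParams(alpha_gain=ag, alpha_loss=0.03, beta=5.0)
            acc = [
                (lambda s: (s.training["choice"] == s.training["pair"].str[0]).mean())(
                    simulate_session(p, cfg, seed=seed)
                )
                for seed in range(30)
            ]
            means.append(np.mean(acc))
        assert means == sorted(means)

    def test_test_phase_slower_than_training(self, default_session):
        s = default_session
        assert s.rt_ms[~s.training_mask()].mean() > s.rt_ms[s.training_mask()].mean()


def test_session_csv_round_trip(tmp_path, default_session):
    trials_path = tmp_path / "session.csv"
    default_session.to_csv(trials_path)
    loaded = BehavioralSession.from_csv(trials_path)
    assert loaded.trials["choice"].tolist() == default_session.trials["choice"].tolist()
    np.testing.assert_allclose(loaded.rpe, default_session.rpe)
    np.testing.assert_allclose(loaded.choice_prob, default_session.choice_prob)


def test_cohort_sampling_is_deterministic_and_bounded():
    a = sample_agent_params(20, seed=5)
    b = sample_agent_params(20, seed=5)
    assert a == b
    assert all(0.01 <= p.alpha_gain <= 0.95 for p in a)
    assert all(1.0 <= p.beta <= 10.0 for p in a)
    sessions = simulate_cohort(3, seed=9)
    assert len(sessions) == 3
    assert simulate_cohort(0, seed=9) == []
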
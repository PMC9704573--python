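"""Agent value updates, choice rules, and behavioural signatures."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep.agent import (
    AgentParams,
    AgentState,
    ParameterError,
    compute_mb_values,
    simulate_condition,
    stage1_choice_probs,
    stage2_choice_probs,
    update_stage1_mf,
    update_stage2_value,
)
from twostep.choice_stats import mb_score, stay_table
from twostep.cohort import _log_from_sim
from twostep.task import TaskConfig


def make_state(q2=None, q_mf=None, prev=None):
    s = AgentState.initial()
    if q2 is not None:
        s = dataclasses.replace(s, q2=np.asarray(q2, dtype=float))
    if q_mf is not None:
        s = dataclasses.replace(s, q_mf=np.asarray(q_mf, dtype=float))
    return dataclasses.replace(s, prev_choice=prev)


class TestValueUpdates:
    @pytest.mark.parametrize("reward,expected", [(1, 1.25), (0, 0.25)])
    def test_decay_plus_reward_update(self, reward, expected):
        # Q <- (1 - alpha) * Q + r with Q = 0.5, alpha = 0.5
        s = update_stage2_value(AgentState.initial(), 0, 0, reward, alpha=0.5)
        assert s.q2[0, 0] == pytest.approx(expected)
        s = update_stage1_mf(AgentState.initial(), 1, reward, alpha=0.5)
        assert s.q_mf[1] == pytest.approx(expected)

    def test_only_visited_entry_updates(self):
        s = update_stage2_value(AgentState.initial(), 1, 0, 1, alpha=0.3)
        untouched = [(0, 0), (0, 1), (1, 1)]
        assert all(s.q2[i] == 0.5 for i in untouched)
        s = update_stage1_mf(AgentState.initial(), 0, 1, alpha=0.3)
        assert s.q_mf[1] == 0.5

    def test_fixed_point_of_constant_reward(self):
        # solving Q = (1 - alpha) Q + 1 gives Q* = 1 / alpha
        s = AgentState.initial()
        for _ in range(200):
            s = update_stage2_value(s, 0, 0, 1, alpha=0.4)
        assert s.q2[0, 0] == pytest.approx(2.5, abs=1e-9)

    def test_reward_sequence_iterated_substitution(self):
        s = AgentState.initial()
        for r in (1, 0, 1):
            s = update_stage1_mf(s, 0, r, alpha=0.5)
        assert s.q_mf[0] == pytest.approx(1.3125)

    def test_alpha_one_is_memoryless_under_delta_rule(self):
        s = make_state(q2=[[0.9, 0.1], [0.2, 0.8]])
        s = update_stage2_value(s, 0, 0, 0, alpha=1 - 1e-12, delta_rule=True)
        assert s.q2[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ParameterError):
            update_stage2_value(AgentState.initial(), 0, 0, 1, alpha=1.5)


class TestChoiceRules:
    def test_zero_temperature_uniform(self):
        s = make_state(q2=[[1.0, 0.0], [0.3, 0.9]])
        assert stage2_choice_probs(s, 0, beta_2=0.0) == pytest.approx([0.5, 0.5])

    def test_softmax_unit_gap(self):
        s = make_state(q2=[[1.0, 0.0], [0.5, 0.5]])
        p = stage2_choice_probs(s, 0, beta_2=1.0)
        assert p[0] == pytest.approx(math.e / (math.e + 1), abs=1e-10)

    def test_greedy_limit(self):
        s = make_state(q2=[[1.0, 0.0], [0.5, 0.5]])
        p = stage2_choice_probs(s, 0, beta_2=500.0)
        assert p == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_mb_values_direct_substitution(self):
        s = make_state(q2=[[0.8, 0.2], [0.3, 0.4]])
        assert compute_mb_values(s, 0.7) == pytest.approx([0.68, 0.52])

    def test_mb_values_flat_and_symmetric(self):
        s = make_state(q2=np.full((2, 2), 0.37))
        assert compute_mb_values(s, 0.7) == pytest.approx([0.37, 0.37])
        rng = np.random.default_rng(0)
        s = make_state(q2=rng.random((2, 2)))
        q = compute_mb_values(s, 0.5)
        assert q[0] == pytest.approx(q[1])

    def test_stage1_uniform_when_all_weights_zero(self):
        p = AgentParams(0.5, 0.0, 0.0, 0.0, 0.0)
        probs = stage1_choice_probs(make_state(prev=0), p)
        assert probs == pytest.approx([0.5, 0.5])

    def test_pure_perseveration_logit(self):
        p = AgentParams(0.5, 0.0, 0.0, 0.0, 1.0)
        probs = stage1_choice_probs(make_state(prev=0), p)
        assert probs[0] == pytest.approx(math.e / (math.e + 1), abs=1e-10)

    def test_mb_weighted_logistic(self):
        # logits 2 * (0.68, 0.52): p(L) = logistic(2 * 0.16)
        p = AgentParams(0.5, 2.0, 0.0, 0.0, 0.0)
        s = make_state(q2=[[0.8, 0.2], [0.3, 0.4]], q_mf=[0.0, 0.0])
        probs = stage1_choice_probs(s, p, 0.7)
        assert probs[0] == pytest.approx(1 / (1 + math.exp(-0.32)), abs=1e-10)

    def test_first_trial_indicator_is_zero(self):
        p = AgentParams(0.5, 0.0, 0.0, 0.0, 5.0)
        probs = stage1_choice_probs(make_state(prev=None), p)
        assert probs == pytest.approx([0.5, 0.5])


@settings(max_examples=50, deadline=None)
@given(
    q2=st.lists(st.floats(-2, 2), min_size=4, max_size=4),
    qmf=st.lists(st.floats(-2, 2), min_size=2, max_size=2),
    beta=st.floats(0, 5),
    rho=st.floats(-4, 4),
    prev=st.sampled_from([None, 0, 1]),
)
def test_choice_probs_are_proper(q2, qmf, beta, rho, prev):
    """Probabilities at both stages are in (0,1) and sum to one.

    Logit gaps are kept moderate so strict openness is representable in
    floating point (extreme gaps round one probability to exactly 1.0).
    """
    s = make_state(q2=np.array(q2).reshape(2, 2), q_mf=qmf, prev=prev)
    params = AgentParams(0.5, beta, beta, beta, rho)
    for probs in (
        stage1_choice_probs(s, params),
        stage2_choice_probs(s, 0, beta),
        stage2_choice_probs(s, 1, beta),
    ):
        assert probs.sum() == pytest.approx(1.0)
        assert (probs > 0).all() and (probs < 1).all()


class TestBehaviouralSignatures:
    def test_random_agent_stays_half_the_time(self, config):
        p = AgentParams(0.5, 0.0, 0.0, 0.0, 0.0)
        rng = np.random.default_rng(1)
        stays = []
        for _ in range(30):
            sim = simulate_condition(p, config, rng)
            c1 = sim["choice1"]
            stays.append(np.mean(c1[1:] == c1[:-1]))
        assert np.mean(stays) == pytest.approx(0.5, abs=0.03)

    def test_model_free_signature_reward_effect(self, config):
        """A pure-MF agent repeats rewarded choices regardless of transition."""
        p = AgentParams(0.6, 0.0, 5.0, 2.0, 0.0)
        rng = np.random.default_rng(2)
        wins = 0
        n = 100
        for _ in range(n):
            sim = simulate_condition(p, config, rng)
            tab = stay_table(_log_from_sim(sim))
            rew = np.nanmean([tab.probs[(1, "common")], tab.probs[(1, "rare")]])
            unrew = np.nanmean([tab.probs[(0, "common")], tab.probs[(0, "rare")]])
            wins += rew > unrew
        assert wins > 0.9 * n  # sign test: overwhelming majority

    def test_model_based_signature_interaction(self, config):
        """A pure-MB agent shows the reward x transition interaction."""
        p = AgentParams(0.6, 5.0, 0.0, 2.0, 0.0)
        rng = np.random.default_rng(3)
        scores = []
        for _ in range(100):
            sim = simulate_condition(p, config, rng)
            scores.append(mb_score(stay_table(_log_from_sim(sim))))
        scores = np.asarray(scores)
        assert np.nanmean(scores) > 0.2
        assert np.mean(scores > 0) > 0.85

    def test_simulation_reproducible(self, config, typical_params):
        a = simulate_condition(typical_params, config, np.random.default_rng(77))
        b = simulate_condition(typical_params, config, np.random.default_rng(77))
        for k in ("choice1", "state2", "choice2", "reward"):
            assert np.array_equal(a[k], b[k])

    def test_transition_labels_consistent(self, config, sim_log):
        log, _ = sim_log
        common = log.transition == "common"
        assert np.array_equal(common, log.choice1 == log.state2)
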
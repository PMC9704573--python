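"""Environment: transition structure and reward-probability random walks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep.task import (
    ConfigurationError,
    RewardWalks,
    TaskConfig,
    generate_walks,
    init_walks,
    sample_reward,
    sample_transition,
    step_walks,
    walks_to_frame,
)


class TestConfig:
    def test_defaults_valid(self, config):
        assert config.p_rare == pytest.approx(0.3)
        assert config.n_blocks == 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_common": 0.5},
            {"p_common": 1.2},
            {"walk_lower": 0.8},
            {"start_range_high": (0.7, 0.6)},
            {"start_range_low": (0.1, 0.4)},
            {"n_trials_per_condition": 100, "block_length": 75},
            {"boundary": "wrap"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            TaskConfig(**kwargs)


class TestInitWalks:
    def test_two_high_two_low_starts(self, config):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = init_walks(config, rng)
            flat = w.probs.ravel()
            assert ((flat >= 0.31) & (flat <= 0.72)).all()
            assert (flat >= 0.58).sum() == 2
            assert (flat <= 0.45).sum() == 2

    def test_degenerate_ranges_give_exact_starts(self):
        cfg = TaskConfig(start_range_high=(0.6, 0.6), start_range_low=(0.4, 0.4))
        w = init_walks(cfg, np.random.default_rng(1))
        assert sorted(w.probs.ravel()) == [0.4, 0.4, 0.6, 0.6]

    def test_high_start_mean_matches_uniform(self, config):
        # oracle: mean of Uniform(0.58, 0.72) = 0.65
        rng = np.random.default_rng(2)
        highs = []
        for _ in range(10_000):
            flat = init_walks(config, rng).probs.ravel()
            highs.extend(flat[flat >= 0.58])
        se = (0.72 - 0.58) / np.sqrt(12 * len(highs))
        assert np.mean(highs) == pytest.approx(0.65, abs=4 * se)

    def test_range_assignment_randomised_across_slots(self, config):
        rng = np.random.default_rng(3)
        high_count = np.zeros(4)
        for _ in range(600):
            high_count += init_walks(config, rng).probs.ravel() >= 0.58
        # each slot should be high roughly half the time
        assert (np.abs(high_count / 600 - 0.5) < 0.1).all()


class TestStepWalks:
    def test_zero_sigma_leaves_walks_unchanged(self):
        cfg = TaskConfig(sigma_walk=0.0)
        w = init_walks(cfg, np.random.default_rng(0))
        for _ in range(20):
            w2 = step_walks(w, cfg, np.random.default_rng(0))
            assert np.array_equal(w2.probs, w.probs)
            w = w2

    def test_reflection_at_upper_bound(self, config):
        # explicit reflection map: r(x) = 2*0.75 - x for x > 0.75
        w = RewardWalks(probs=np.full((2, 2), 0.749))

        class FixedRng:
            def normal(self, loc, scale, size):
                return np.full(size, 0.01)

        out = step_walks(w, config, FixedRng())
        assert out.probs == pytest.approx(np.full((2, 2), 0.741))

    def test_increment_sd_matches_volatility(self, config):
        # stepping from the interval centre never reflects (25 sigma away),
        # so each observed difference is a raw Gaussian increment
        rng = np.random.default_rng(4)
        centre = RewardWalks(probs=np.full((2, 2), 0.5))
        incs = []
        for _ in range(25_000):
            w2 = step_walks(centre, config, rng)
            incs.extend((w2.probs - 0.5).ravel())
        assert np.std(incs) == pytest.approx(0.0275, rel=0.02)

    def test_bounds_never_violated_long_run(self, config):
        rng = np.random.default_rng(5)
        w = init_walks(config, rng)
        lo, hi = 1.0, 0.0
        for _ in range(10_000):
            w = step_walks(w, config, rng)
            lo = min(lo, w.probs.min())
            hi = max(hi, w.probs.max())
        assert lo >= 0.25 and hi <= 0.75

    def test_clip_boundary_mode(self):
        cfg = TaskConfig(boundary="clip")
        w = RewardWalks(probs=np.full((2, 2), 0.749))

        class FixedRng:
            def normal(self, loc, scale, size):
                return np.full(size, 0.05)

        out = step_walks(w, cfg, FixedRng())
        assert (out.probs == 0.75).all()

    def test_stationary_mean_near_midpoint(self, config):
        # reflection keeps the stationary distribution symmetric about 0.5
        rng = np.random.default_rng(6)
        w = RewardWalks(probs=np.full((2, 2), 0.5))
        total = 0.0
        n = 20_000
        for _ in range(n):
            w = step_walks(w, config, rng)
            total += w.probs.mean()
        assert total / n == pytest.approx(0.5, abs=0.03)


class TestTransitions:
    def test_deterministic_limit(self):
        cfg = TaskConfig(p_common=1.0)
        rng = np.random.default_rng(0)
        for choice in (0, 1):
            state, label = sample_transition(choice, cfg, rng)
            assert state == choice and label == "common"

    def test_common_rate_and_symmetry(self, config):
        rng = np.random.default_rng(7)
        n = 100_000
        hits_l = sum(sample_transition(0, config, rng)[0] == 0 for _ in range(n))
        hits_r = sum(sample_transition(1, config, rng)[0] == 1 for _ in range(n))
        se = np.sqrt(0.7 * 0.3 / n)
        assert hits_l / n == pytest.approx(0.7, abs=3 * se)
        assert hits_r / n == pytest.approx(0.7, abs=3 * se)

    def test_label_consistent_with_state(self, config):
        rng = np.random.default_rng(8)
        for _ in range(200):
            choice = int(rng.random() < 0.5)
            state, label = sample_transition(choice, config, rng)
            assert (label == "common") == (state == choice)

    def test_invalid_choice_rejected(self, config):
        with pytest.raises(ValueError):
            sample_transition(2, config, np.random.default_rng(0))


class TestRewards:
    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(9)
        w0 = RewardWalks(probs=np.zeros((2, 2)))
        w1 = RewardWalks(probs=np.ones((2, 2)))
        assert all(sample_reward(0, 0, w0, rng) == 0 for _ in range(100))
        assert all(sample_reward(1, 1, w1, rng) == 1 for _ in range(100))

    def test_bernoulli_frequency(self):
        rng = np.random.default_rng(10)
        w = RewardWalks(probs=np.full((2, 2), 0.5))
        n = 100_000
        freq = sum(sample_reward(0, 1, w, rng) for _ in range(n)) / n
        assert freq == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))


def test_trajectory_shape_and_export(config):
    traj = generate_walks(config, np.random.default_rng(11))
    assert traj.shape == (150, 2, 2)
    assert traj.min() >= 0.25 and traj.max() <= 0.75
    df = walks_to_frame(traj)
    assert list(df.columns) == ["trial", "state", "chest", "p_reward"]
    assert len(df) == 600
    assert df["trial"].min() == 1 and df["trial"].max() == 150


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_walks_reproducible_and_bounded(seed):
    cfg = TaskConfig()
    a = generate_walks(cfg, np.random.default_rng(seed), n_trials=50)
    b = generate_walks(cfg, np.random.default_rng(seed), n_trials=50)
    assert np.array_equal(a, b)
    assert a.min() >= 0.25 and a.max() <= 0.75
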
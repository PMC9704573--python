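"""Stay probabilities, MB score, regression design, covariate correlations."""

import numpy as np
import pandas as pd
import pytest

from twostep.choice_stats import (
    CELLS,
    StayTable,
    build_stay_regression,
    correlate_delta_with_covariates,
    delta_beta_mb,
    mb_score,
    stay_table,
    stay_tables_frame,
)
from twostep.cohort import ConditionLog


def make_log(choice1, reward, transition, block=None):
    n = len(choice1)
    return ConditionLog(
        choice1=np.asarray(choice1, dtype=np.int64),
        transition=np.asarray(transition, dtype=object),
        state2=np.zeros(n, dtype=np.int64),
        choice2=np.zeros(n, dtype=np.int64),
        reward=np.asarray(reward, dtype=np.int64),
        block=np.asarray(block if block is not None else np.ones(n), dtype=np.int64),
    )


class TestStayTable:
    def test_always_repeating_agent(self):
        # rewards/transitions arranged so all four (reward, transition) cells occur
        log = make_log([0] * 20, [1, 1, 0, 0] * 5, ["common", "rare"] * 10)
        tab = stay_table(log)
        assert all(tab.counts[c] > 0 for c in CELLS)
        assert all(tab.probs[c] == 1.0 for c in CELLS)

    def test_always_alternating_agent(self):
        log = make_log([0, 1] * 10, [1, 0] * 10, ["common", "rare"] * 10)
        tab = stay_table(log)
        for c in CELLS:
            if tab.counts[c] > 0:
                assert tab.probs[c] == 0.0

    def test_toy_log_hand_count(self):
        # trials:      1        2        3        4        5        6
        # choice1:     L        L        R        R        R        L
        # prev (r,t):  -     (1,com)  (0,rare) (1,com)  (0,com)  (1,rare)
        log = make_log(
            [0, 0, 1, 1, 1, 0],
            [1, 0, 1, 0, 1, 1],
            ["common", "rare", "common", "common", "rare", "common"],
        )
        tab = stay_table(log)
        assert tab.probs[(1, "common")] == pytest.approx(1.0)  # pairs into trials 2 and 4
        assert tab.counts[(1, "common")] == 2
        assert tab.probs[(0, "rare")] == 0.0 and tab.counts[(0, "rare")] == 1
        assert tab.probs[(0, "common")] == 1.0 and tab.counts[(0, "common")] == 1
        assert tab.probs[(1, "rare")] == 0.0 and tab.counts[(1, "rare")] == 1

    def test_block_break_pairs_excluded(self):
        log = make_log([0] * 6, [1] * 6, ["common"] * 6, block=[1, 1, 1, 2, 2, 2])
        tab = stay_table(log)
        assert sum(tab.counts.values()) == 4  # 5 pairs minus the cross-break one

    def test_counts_sum_to_pairs(self, sim_log):
        log, _ = sim_log
        tab = stay_table(log)
        # 150 trials in two 75-trial blocks: 148 within-block pairs
        assert sum(tab.counts.values()) == 148

    def test_zero_denominator_cell_is_nan(self):
        log = make_log([0, 0, 0], [1, 1, 1], ["common", "common", "common"])
        tab = stay_table(log)
        assert np.isnan(tab.probs[(0, "rare")])
        assert not tab.complete

    def test_all_missing_log_rejected(self):
        log = make_log([-1] * 10, [-1] * 10, [""] * 10)
        with pytest.raises(ValueError):
            stay_table(log)


class TestMbScore:
    def test_equal_cells_score_zero(self):
        tab = StayTable(probs={c: 0.7 for c in CELLS}, counts={c: 5 for c in CELLS})
        assert mb_score(tab) == pytest.approx(0.0)

    def test_perfect_model_based_pattern(self):
        probs = {(1, "common"): 1.0, (1, "rare"): 0.0, (0, "common"): 0.0, (0, "rare"): 1.0}
        tab = StayTable(probs=probs, counts={c: 5 for c in CELLS})
        assert mb_score(tab) == pytest.approx(2.0)

    def test_direct_substitution(self):
        probs = {(1, "common"): 0.9, (1, "rare"): 0.7, (0, "common"): 0.6, (0, "rare"): 0.65}
        tab = StayTable(probs=probs, counts={c: 5 for c in CELLS})
        assert mb_score(tab) == pytest.approx(0.25)

    def test_antisymmetric_under_reward_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(4)
            tab = StayTable(probs=dict(zip(CELLS, p)), counts={c: 1 for c in CELLS})
            swapped = StayTable(
                probs={(1 - r, t): v for (r, t), v in tab.probs.items()},
                counts=tab.counts,
            )
            assert mb_score(swapped) == pytest.approx(-mb_score(tab))

    def test_undefined_cell_propagates(self):
        probs = {(1, "common"): 1.0, (1, "rare"): float("nan"),
                 (0, "common"): 0.0, (0, "rare"): 1.0}
        tab = StayTable(probs=probs, counts={c: 1 for c in CELLS})
        assert np.isnan(mb_score(tab))


class TestDeltaBetaMb:
    def test_examples(self):
        assert delta_beta_mb(1.0, 1.0) == 0.0
        assert delta_beta_mb(0.8, 1.42) == pytest.approx(-0.62)

    def test_sign_convention(self):
        # lower model-based weight under BID gives a negative delta
        assert delta_beta_mb(0.5, 1.5) < 0


class TestRegressionDesign:
    def test_codings(self, small_cohort):
        df = build_stay_regression(small_cohort)
        assert set(df["reward"]) <= {-1, 1}
        assert set(df["transition"]) <= {-1, 1}
        assert set(df["stay"]) <= {0, 1}
        # product coding of the interaction
        rewarded_common = df[(df["reward"] == 1) & (df["transition"] == 1)]
        assert ((rewarded_common["reward"] * rewarded_common["transition"]) == 1).all()
        unrew_rare = df[(df["reward"] == -1) & (df["transition"] == -1)]
        assert ((unrew_rare["reward"] * unrew_rare["transition"]) == 1).all()

    def test_row_count_excludes_block_firsts(self, small_cohort):
        df = build_stay_regression(small_cohort)
        # per subject-condition: 150 trials, two blocks -> 148 pairs
        assert len(df) == len(small_cohort) * 2 * 148

    def test_age_z_standardised(self, small_cohort):
        df = build_stay_regression(small_cohort)
        per_subject = df.groupby("subject_id")["age_z"].first()
        assert per_subject.mean() == pytest.approx(0.0, abs=1e-9)
        assert per_subject.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_group_condition_indicators(self, small_cohort):
        df = build_stay_regression(small_cohort)
        assert ((df["group"] == "ED") == (df["group_ed"] == 1)).all()
        assert ((df["condition"] == "BID") == (df["condition_bid"] == 1)).all()

    def test_missing_condition_rejected(self, small_cohort):
        broken = small_cohort[0]
        trials = dict(broken.trials)
        trials.pop("BID")
        import dataclasses

        bad = dataclasses.replace(broken, trials=trials)
        with pytest.raises(ValueError, match="lacks condition"):
            build_stay_regression([bad])


class TestCorrelations:
    def test_perfect_linear_relationship(self):
        delta = np.linspace(-1, 1, 20)
        cov = pd.DataFrame({"eat26": 3 + 2 * delta})
        out = correlate_delta_with_covariates(delta, cov)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-10

    def test_zero_variance_flagged(self):
        delta = np.linspace(-1, 1, 10)
        cov = pd.DataFrame({"aai": np.full(10, 5.0)})
        out = correlate_delta_with_covariates(delta, cov)
        assert not out.loc[0, "defined"]
        assert np.isnan(out.loc[0, "r"])

    def test_permutation_null_p_uniform(self):
        """Correlating with shuffled copies gives uniform p-values."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        ps = []
        for _ in range(500):
            y = rng.permutation(x)
            out = correlate_delta_with_covariates(x, pd.DataFrame({"c": y}))
            ps.append(out.loc[0, "p"])
        ps = np.sort(ps)
        # Kolmogorov-Smirnov distance from Uniform(0,1)
        ks = np.max(np.abs(ps - (np.arange(1, 501) - 0.5) / 500))
        assert ks < 1.63 / np.sqrt(500)  # alpha = 0.01 critical value

    def test_matches_exact_t_transform(self):
        rng = np.random.default_rng(6)
        delta = rng.normal(size=30)
        cov = pd.DataFrame({"ocir": 0.4 * delta + rng.normal(size=30)})
        out = correlate_delta_with_covariates(delta, cov)
        r = out.loc[0, "r"]
        t = r * np.sqrt((30 - 2) / (1 - r**2))
        from scipy import stats

        p = 2 * stats.t.sf(abs(t), 28)
        assert out.loc[0, "p"] == pytest.approx(p, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_delta_with_covariates([1.0, 2.0], pd.DataFrame({"a": [1, 2]}))


def test_stay_tables_frame_columns(small_cohort):
    df = stay_tables_frame(small_cohort[:3])
    assert len(df) == 6  # 3 subjects x 2 conditions
    assert "mb_score" in df.columns
    assert {"p_stay_rew_common", "p_stay_unrew_rare"} <= set(df.columns)
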
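"""Statistical layer: tests against closed-form and enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tovaqeeg.stats import (
    bootstrap_mean_ci,
    bootstrap_means,
    channelwise_ttests,
    combine_scores,
    mann_whitney,
    roc,
    spearman,
    sweep_combination_weights,
    two_way_anova_bonferroni,
)


class TestMannWhitney:
    def test_identical_groups_not_significant(self):
        res = mann_whitney([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.pvalue >= 0.99

    def test_fully_separated_small_groups_exact_p(self):
        """A={1,2,3}, B={10,11,12}: U=0 and exact two-sided p = 2/20."""
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    def test_power_against_simulation_oracle(self):
        """Rejection rate under a known shift tracks a Monte-Carlo oracle
        computed with an independent rank-sum implementation."""
        rng = np.random.default_rng(42)
        n, shift, sims = 15, 1.2, 400
        rejections = 0
        oracle_rejections = 0
        for _ in range(sims):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n) + shift
            rejections += mann_whitney(a, b).pvalue < 0.05
            # oracle: normal approximation from first principles
            ranks = sps.rankdata(np.concatenate([a, b]))
            u = ranks[:n].sum() - n * (n + 1) / 2
            mu, sd = n * n / 2, np.sqrt(n * n * (2 * n + 1) / 12)
            p = 2 * sps.norm.sf(abs(u - mu) / sd)
            oracle_rejections += p < 0.05
        assert abs(rejections - oracle_rejections) / sims < 0.05


class TestTwoWayAnova:
    def test_all_equal_values_give_zero_f(self):
        values = [5.0] * 12
        group = ["a"] * 6 + ["b"] * 6
        cond = ["x", "x", "y", "y", "z", "z"] * 2
        res = two_way_anova_bonferroni(values, group, cond)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.estimates["group"]["F"] == pytest.approx(0.0, abs=1e-10)

    def test_balanced_design_matches_hand_computed_table(self):
        """2x3 design, two observations per cell at mu_ij -+ 1: F statistics
        from the closed-form sums of squares."""
        mu = {("a", "x"): 1.0, ("a", "y"): 3.0, ("a", "z"): 5.0,
              ("b", "x"): 2.0, ("b", "y"): 6.0, ("b", "z"): 10.0}
        rows = [(g, c, m + d) for (g, c), m in mu.items() for d in (-1.0, 1.0)]
        df = pd.DataFrame(rows, columns=["group", "cond", "value"])

        # closed-form two-way ANOVA with replication (balanced, n=2)
        n = 2
        grand = df["value"].mean()
        g_means = df.groupby("group")["value"].mean()
        c_means = df.groupby("cond")["value"].mean()
        cell_means = df.groupby(["group", "cond"])["value"].mean()
        ss_g = 3 * n * ((g_means - grand) ** 2).sum()
        ss_c = 2 * n * ((c_means - grand) ** 2).sum()
        ss_cells = n * ((cell_means - grand) ** 2).sum()
        ss_i = ss_cells - ss_g - ss_c
        ss_e = sum((row.value - cell_means[(row.group, row.cond)]) ** 2
                   for row in df.itertuples())
        ms_e = ss_e / (12 - 6)
        res = two_way_anova_bonferroni(df["value"], df["group"], df["cond"])
        assert res.estimates["group"]["F"] == pytest.approx(ss_g / 1 / ms_e)
        assert res.estimates["condition"]["F"] == pytest.approx(
            ss_c / 2 / ms_e)
        assert res.estimates["interaction"]["F"] == pytest.approx(
            ss_i / 2 / ms_e)

    def test_bonferroni_adjustment_is_k_times_p(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "value": rng.standard_normal(30),
            "group": ["a", "b"] * 15,
            "cond": ["x"] * 10 + ["y"] * 10 + ["z"] * 10,
        })
        res = two_way_anova_bonferroni(df["value"], df["group"], df["cond"])
        assert len(res.posthoc) == 3
        for row in res.posthoc.itertuples():
            assert row.p_adj == pytest.approx(min(1.0, 3 * row.p_raw))

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            two_way_anova_bonferroni([1, 2, 3, 4],
                                     ["a", "a", "b", "b"],
                                     ["x", "x", "x", "y"])


class TestChannelwiseTTests:
    @staticmethod
    def tidy(values_a, values_b, channel="F7", condition="resting"):
        rows = []
        for g, vals in (("control", values_a), ("mdd", values_b)):
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             "condition": condition, "channel": channel,
                             "band": "theta", "value": v, "metric":
                             "cordance"})
        return pd.DataFrame(rows)

    def test_identical_groups_give_t_zero(self):
        df = self.tidy([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = channelwise_ttests(df)
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_pooled_formula(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(18), rng.standard_normal(18) + 0.8
        out = channelwise_ttests(self.tidy(a, b))
        sp = np.sqrt(((a.var(ddof=1) * 17) + (b.var(ddof=1) * 17)) / 34)
        t_hand = (b.mean() - a.mean()) / (sp * np.sqrt(2 / 18))
        assert out.loc[0, "t"] == pytest.approx(t_hand)

    def test_requested_channels_give_one_row_each(self):
        frames = [self.tidy([1, 2, 3], [2, 3, 4], channel=ch)
                  for ch in ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")]
        out = channelwise_ttests(pd.concat(frames, ignore_index=True),
                                 channels=["Fp1", "Fp2", "F7", "F3", "Fz",
                                           "F4", "F8"])
        assert len(out) == 7


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman(x, x**3).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_constant_input_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.statistic)
        assert res.note is not None

    def test_type_one_error_against_permutation_oracle(self):
        """Under a permutation null at n=18, rejection ~ 5%."""
        rng = np.random.default_rng(0)
        sims, alpha = 2000, 0.05
        rej = sum(spearman(rng.standard_normal(18),
                           rng.standard_normal(18)).pvalue < alpha
                  for _ in range(sims))
        assert 0.03 <= rej / sims <= 0.07


class TestROC:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.cutoff_sensitivity == 1.0
        assert r.cutoff_specificity == 1.0

    def test_four_point_enumeration(self):
        """Scores {1,2,3,4}, labels {0,0,1,1}: AUC = 1, cutoff in (2, 3)."""
        r = roc([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert 2.0 < r.cutoff < 3.0

    def test_sign_symmetry(self, rng):
        scores = rng.standard_normal(60)
        labels = rng.integers(0, 2, 60)
        while labels.sum() in (0, 60):
            labels = rng.integers(0, 2, 60)
        a = roc(scores, labels).auc
        b = roc(-scores, labels).auc
        assert a == pytest.approx(1.0 - b)

    def test_random_scores_near_half(self, rng):
        scores = rng.standard_normal(4000)
        labels = rng.integers(0, 2, 4000)
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_rank_statistic(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        while labels.sum() in (0, 40):
            labels = rng.integers(0, 2, 40)
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc(scores, labels).auc == pytest.approx(
            u / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [1, 1, 1])


class TestCombination:
    def test_weight_zero_returns_apen(self, rng):
        a = rng.random(10)
        o = rng.random(10)
        assert np.array_equal(combine_scores(a, o, 0.0), a)

    def test_sweep_evaluates_eleven_weights(self, rng):
        a = rng.random(20)
        o = rng.random(20)
        labels = rng.integers(0, 2, 20)
        while labels.sum() in (0, 20):
            labels = rng.integers(0, 2, 20)
        out = sweep_combination_weights(a, o, labels)
        assert len(out) == 11
        assert out["best"].sum() >= 1

    def test_informative_omission_pushes_best_weight_up(self, rng):
        """When omission separates groups better than the entropy score,
        the sweep prefers a positive weight."""
        n = 40
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        apen = rng.standard_normal(n) * 1.0 + 0.2 * labels
        omission = rng.standard_normal(n) * 1.0 + 3.0 * labels
        out = sweep_combination_weights(apen, omission, labels)
        assert float(out.loc[out["best"], "weight"].iloc[0]) > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_scores([1, 2], [1, 2, 3], 0.5)


class TestBootstrap:
    @staticmethod
    def cells(rng, n=12):
        return {(g, c): rng.standard_normal(n) + dict(
            resting=0.0, target=1.0, nontarget=2.0)[c]
            for g in ("control", "mdd")
            for c in ("resting", "target", "nontarget")}

    def test_degenerate_cell_gives_zero_width(self, rng):
        cells = self.cells(rng)
        cells[("control", "resting")] = np.full(10, 3.0)
        res = bootstrap_means(cells, B=100, seed=1)
        m = res.means[("control", "resting")]
        assert np.all(m == 3.0)

    def test_resampled_means_follow_clt(self, rng):
        x = rng.standard_normal(50) * 2.0 + 5.0
        means, _ = bootstrap_mean_ci(x, B=4000, seed=2)
        assert means.mean() == pytest.approx(x.mean(), abs=0.05)
        assert means.std() == pytest.approx(x.std() / np.sqrt(50), rel=0.1)

    def test_six_cells_give_fifteen_pairwise_comparisons(self, rng):
        res = bootstrap_means(self.cells(rng), B=50, seed=3)
        assert len(res.pairwise) == 15

    def test_same_seed_bit_reproducible(self, rng):
        cells = self.cells(rng)
        a = bootstrap_means(cells, B=200, seed=7)
        b = bootstrap_means(cells, B=200, seed=7)
        for key in cells:
            assert np.array_equal(a.means[key], b.means[key])

    def test_roc_on_bootstrapped_means_per_condition(self, rng):
        res = bootstrap_means(self.cells(rng), B=100, seed=4)
        assert set(res.roc) == {"resting", "target", "nontarget"}
        for r in res.roc.values():
            assert 0.0 <= r.auc <= 1.0

    def test_b_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_means(self.cells(rng), B=1, seed=0)

    def test_crossover_interaction_recovered(self, crossover_study):
        """On cohorts built with the crossover preset the group x condition
        interaction is significant at alpha = 0.01 in >= 90% of cohorts, and
        the Bonferroni contrasts flag the task conditions, not rest."""
        hits = 0
        task_sig = rest_sig = 0
        n_cohorts = crossover_study["cohort"].nunique()
        for _, sub in crossover_study.groupby("cohort"):
            res = two_way_anova_bonferroni(sub["apen"], sub["group"],
                                           sub["condition"], alpha=0.01)
            hits += res.pvalue < 0.01
            ph = res.posthoc.set_index("condition")
            task_sig += (ph.loc["target", "p_adj"] < 0.05
                         and ph.loc["nontarget", "p_adj"] < 0.05)
            rest_sig += ph.loc["resting", "p_adj"] < 0.05
        assert hits >= 0.9 * n_cohorts
        assert task_sig >= 0.9 * n_cohorts
        assert rest_sig <= 0.5 * n_cohorts

    def test_ci_coverage_near_nominal(self):
        """Percentile bootstrap CI covers the true mean ~95% of the time on
        Gaussian samples (500 replicates)."""
        rng = np.random.default_rng(11)
        n, reps, covered = 30, 500, 0
        for k in range(reps):
            x = rng.standard_normal(n)
            _, (lo, hi) = bootstrap_mean_ci(x, B=1000, seed=k)
            covered += lo <= 0.0 <= hi
        assert 0.92 <= covered / reps <= 0.98
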
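"""Two-scale approximate entropy: oracle equivalence and invariances."""

import dataclasses

import numpy as np
import pytest

import tovaqeeg as tq
from tovaqeeg.apen import ApEnConfig, apen_component, apen_score, reshape_image
from tovaqeeg.covimg import CovarianceImage, covariance_image, to_image
from tovaqeeg.epochs import resting_segment


def brute_force_component(sn, m, r, norm="chebyshev",
                          include_self_matches=True):
    """Literal O(n^2) double-loop enumeration of the match fraction."""
    sn = np.asarray(sn, float)
    n = sn.size
    nw = n - m + 1
    total = 0
    for i in range(nw):
        pi = sn[i:i + m]
        count = 0
        for j in range(nw):
            pj = sn[j:j + m]
            if not include_self_matches and i == j:
                continue
            if norm == "chebyshev":
                d = np.max(np.abs(pi - pj))
            else:
                d = np.sqrt(np.sum((pi - pj) ** 2))
            if d < r:
                count += 1
        total += count / nw
    return total / nw


def image_from_matrix(mat):
    image8, equalized = to_image(mat)
    return CovarianceImage(np.asarray(mat, float), image8, equalized, 1)


class TestReshape:
    def test_19x19_flattens_to_361(self, rng):
        sn = reshape_image(rng.random((19, 19)))
        assert sn.shape == (361,)

    def test_diagonal_elements_are_20_apart(self, rng):
        img = rng.random((19, 19))
        sn = reshape_image(img)
        diag_idx = np.arange(19) * 20
        assert np.array_equal(sn[diag_idx], np.diag(img))

    def test_row_major_order(self):
        sn = reshape_image(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert list(sn) == [1.0, 2.0, 3.0, 4.0]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            reshape_image(np.zeros((3, 4)))


class TestComponent:
    def test_constant_sequence_all_match(self):
        assert apen_component(np.full(30, 5.0), 4, 0.1) == 1.0

    def test_r_above_range_all_match(self, rng):
        sn = rng.random(40)
        assert apen_component(sn, 5, 2.0) == 1.0

    def test_alternating_sequence_against_enumeration(self):
        """Two interleaved window patterns; exhaustive pair count oracle."""
        sn = np.array([0.0, 100.0] * 4)
        got = apen_component(sn, 2, 1.0)
        assert got == pytest.approx(brute_force_component(sn, 2, 1.0))
        # 7 windows alternate (0,100) / (100,0); each matches its own
        # phase: 4 and 3 windows respectively
        assert got == pytest.approx((4 * 4 + 3 * 3) / 49)

    @pytest.mark.parametrize("m", [2, 5, 10])
    @pytest.mark.parametrize("norm", ["chebyshev", "euclidean"])
    def test_matches_brute_force_oracle(self, m, norm):
        """Vectorized component equals the O(n^2) loop, 50 random cases."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(m + 2, 61))
            sn = np.round(rng.random(n) * 10, 2)
            r = float(rng.uniform(0.05, 2.0))
            assert apen_component(sn, m, r, norm=norm) == pytest.approx(
                brute_force_component(sn, m, r, norm=norm), abs=1e-12)

    def test_self_match_exclusion_matches_oracle(self):
        rng = np.random.default_rng(3)
        sn = rng.random(40)
        got = apen_component(sn, 3, 0.5, include_self_matches=False)
        want = brute_force_component(sn, 3, 0.5, include_self_matches=False)
        assert got == pytest.approx(want)

    def test_m_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apen_component(np.ones(10), 10, 0.5)


class TestScore:
    def test_constant_image_gives_unit_ratio(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            img = image_from_matrix(np.full((19, 19), 0.3))
        score = apen_score(img)
        assert score.component_m1 == 1.0
        assert score.component_m2 == 1.0
        assert score.value == pytest.approx(1 / 361)

    def test_m2_matches_are_subset_of_m1_matches(self, rng):
        """Under the max norm a match of two long windows implies a match
        of their prefixes (verified exhaustively on random 6x6 images)."""
        for _ in range(20):
            sn = reshape_image(rng.random((6, 6)))
            r = 0.3 * sn.std()
            n = sn.size
            m1, m2 = 3, 8
            for i in range(n - m2 + 1):
                for j in range(n - m2 + 1):
                    long_match = np.max(np.abs(sn[i:i + m2]
                                               - sn[j:j + m2])) < r
                    short_match = np.max(np.abs(sn[i:i + m1]
                                                - sn[j:j + m1])) < r
                    assert short_match or not long_match

    def test_shift_invariance(self, rng):
        mat = rng.random((19, 19))
        cfg = ApEnConfig(source="raw")
        a = apen_score(image_from_matrix(mat), cfg)
        b = apen_score(image_from_matrix(mat + 123.0), cfg)
        assert a.value == pytest.approx(b.value)

    def test_positive_rescaling_invariance_with_sd_relative_r(self, rng):
        """r scales with the sequence SD, so gain cancels exactly."""
        mat = rng.random((19, 19))
        cfg = ApEnConfig(source="raw")
        a = apen_score(image_from_matrix(mat), cfg)
        b = apen_score(image_from_matrix(mat * 7.5), cfg)
        assert a.value == pytest.approx(b.value)

    def test_components_stored_and_ratio_reconstructable(self, rng):
        mat = rng.random((19, 19))
        score = apen_score(image_from_matrix(mat))
        assert score.value == pytest.approx(
            score.component_m1 / score.component_m2 / 361)

    def test_smooth_vs_random_mixing_score_ordering(self):
        """Images from the smooth covariance kernel score at or below images
        from random mixing, across seeds."""
        smooth_wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            m_s = tq.mixing_matrix(1.0, rng)
            m_r = tq.mixing_matrix(0.0, rng)
            v = {}
            for name, m in (("smooth", m_s), ("random", m_r)):
                x = m @ np.random.default_rng(seed + 1).standard_normal(
                    (19, 4000))
                c = x @ x.T
                v[name] = apen_score(image_from_matrix(c / np.trace(c))).value
            smooth_wins += v["smooth"] <= v["random"]
        assert smooth_wins >= 0.9 * n_seeds

    def test_monotone_discrimination_across_regularity(self, clean_profiles):
        """Spearman correlation between irregularity (1 - regularity) and
        the entropy score exceeds 0.8 over 40 synthetic subjects."""
        from scipy.stats import spearmanr
        spec = tq.CohortSpec(rest_duration=40.0)
        rng = np.random.default_rng(0)
        rhos = np.linspace(0.05, 0.95, 40)
        scores = []
        for k, rho in enumerate(rhos):
            prof = dataclasses.replace(clean_profiles["control"],
                                       covariance_regularity_rest=float(rho))
            rec = tq.simulate_recording(None, prof, spec, seed=300 + k,
                                        state="resting")
            img = covariance_image(resting_segment(rec), "resting")
            scores.append(apen_score(img).value)
        corr = spearmanr(1 - rhos, scores).statistic
        assert corr > 0.8

    def test_crossover_preset_orderings(self, crossover_study):
        """Group-mean score pattern: patient > control during the task,
        control > patient at rest, in nearly all seeded cohorts."""
        ok = 0
        n_cohorts = crossover_study["cohort"].nunique()
        for _, sub in crossover_study.groupby("cohort"):
            m = sub.groupby(["group", "condition"])["apen"].mean()
            ok += (m["mdd", "target"] > m["control", "target"]
                   and m["mdd", "nontarget"] > m["control", "nontarget"]
                   and m["control", "resting"] > m["mdd", "resting"])
        assert ok >= 0.9 * n_cohorts
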
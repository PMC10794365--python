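"""ROC/AUC machinery, correlation and descriptive-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vrtpipe.diagnostics import (
    bootstrap_auc_ci,
    chisq_yates,
    ci_encompassment,
    delong_unpaired,
    icc_oneway,
    roc_auc,
    spearman_matrix,
    welch_t,
    youden_cutoff,
)


def brute_force_auc(scores, labels):
    """Exhaustive positive/negative pair counting with ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        c = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert c.auc == 1.0

    def test_small_examples(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, size=20).astype(float)  # ties likely
        labels = rng.random(20) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestBootstrapCi:
    def test_perfect_separation_degenerate_interval(self):
        scores = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        labels = scores > 5
        lo, hi = bootstrap_auc_ci(scores, labels, reps=200, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=60)
        labels = np.arange(60) < 25
        a = bootstrap_auc_ci(scores, labels, reps=500, seed=77)
        b = bootstrap_auc_ci(scores, labels, reps=500, seed=77)
        assert a == b

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="reps"):
            bootstrap_auc_ci([1.0, 2.0], [0, 1], reps=50)


class TestDeLong:
    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = np.arange(40) < 15
        c = roc_auc(scores, labels)
        d, df, p = delong_unpaired(c, c)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s1, l1 = rng.normal(1, 1, 30), np.arange(30) < 14
        s2, l2 = rng.normal(0.5, 1, 26), np.arange(26) < 12
        base = delong_unpaired(roc_auc(s1, l1), roc_auc(s2, l2))
        trans = delong_unpaired(roc_auc(np.exp(s1), l1), roc_auc(np.exp(s2), l2))
        assert base == pytest.approx(trans, abs=1e-12)

    def test_matches_independent_reference_implementation(self):
        """Frozen oracle values computed with the pROC reference on this fixture."""
        a_pos = [2.229, 2.842, 2.347, 0.227, -0.193, 1.267, 2.061, 1.709, 3.01, 1.951, 1.84, 0.469]
        a_neg = [-1.108, 1.484, 0.049, 0.812, -1.376, -0.436, -1.291, -0.776, 0.903, -1.481]
        b_pos = [0.266, 0.964, 0.132, 0.548, 0.578, 1.218, 0.369, 1.072, 0.857]
        b_neg = [0.425, 0.225, 1.658, -0.664, 1.199, -0.403, -0.958, 1.211, -0.44, -0.388, -1.389]
        ca = roc_auc(a_pos + a_neg, [True] * 12 + [False] * 10)
        cb = roc_auc(b_pos + b_neg, [True] * 9 + [False] * 11)
        assert ca.auc == pytest.approx(0.9083333333, abs=1e-9)
        assert cb.auc == pytest.approx(0.7070707071, abs=1e-9)
        d, df, p = delong_unpaired(ca, cb)
        assert d == pytest.approx(1.3971924187, abs=1e-8)
        assert df == pytest.approx(26.8804676404, abs=1e-7)
        assert p == pytest.approx(0.1737834835, abs=1e-8)

    def test_tiny_groups_rejected(self):
        c_ok = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        c_bad = roc_auc([1, 2, 3], [0, 0, 1])
        with pytest.raises(ValueError, match="at least 2"):
            delong_unpaired(c_ok, c_bad)


class TestYouden:
    def test_perfect_separation(self):
        c = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        cut, sens, spec = youden_cutoff(c)
        assert sens == 1.0 and spec == 1.0
        assert 3 < cut < 10

    def test_matches_exhaustive_cut_search(self):
        scores = np.array([1, 2, 3, 4], dtype=float)
        labels = np.array([0, 1, 0, 1], dtype=bool)
        c = roc_auc(scores, labels)
        cut, sens, spec = youden_cutoff(c)
        # brute force over the 5 cut positions
        best_j = -np.inf
        for cand in [0.5, 1.5, 2.5, 3.5, 4.5]:
            s = (scores[labels] > cand).mean()
            sp = (scores[~labels] <= cand).mean()
            best_j = max(best_j, s + sp - 1)
        assert sens + spec - 1 == pytest.approx(best_j)

    def test_j_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = np.arange(50) < 20
        c1 = roc_auc(scores, labels)
        c2 = roc_auc(np.exp(scores), labels)
        _, s1, p1 = youden_cutoff(c1)
        _, s2, p2 = youden_cutoff(c2)
        assert (s1, p1) == pytest.approx((s2, p2))

    def test_cutoff_is_midpoint_between_observed_scores(self):
        c = roc_auc([1, 2, 10, 11], [0, 0, 1, 1])
        cut, sens, spec = youden_cutoff(c)
        assert cut == pytest.approx(6.0)  # midpoint of the adjacent scores 2 and 10

    def test_tie_resolves_to_higher_specificity(self):
        # J = 0.5 at cuts 1.5 and 3.5; the higher cut has specificity 1
        c = roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        cut, sens, spec = youden_cutoff(c)
        assert cut == pytest.approx(3.5)
        assert spec == 1.0


class TestEncompassment:
    def test_published_fixture_not_encompassed(self):
        assert ci_encompassment((0.8008, 0.9725), (0.6667, 0.9333)) is False

    def test_unit_interval_encompasses_everything(self):
        assert ci_encompassment((0.0, 1.0), (0.6667, 0.9333)) is True

    def test_equal_intervals_encompass(self):
        assert ci_encompassment((0.2, 0.8), (0.2, 0.8)) is True


class TestSpearman:
    def test_monotone_and_antitone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        df = pd.DataFrame({"x": x, "cube": x**3, "neg": -x})
        rho, n, p = spearman_matrix(df)
        assert rho.loc["x", "cube"] == pytest.approx(1.0)
        assert rho.loc["x", "neg"] == pytest.approx(-1.0)
        assert (n.loc["x", "cube"]) == 5

    def test_hand_ranked_tie_oracle(self):
        # ranks of y with the tie averaged: [1, 3, 2, 4.5, 4.5, 6];
        # Pearson of [1..6] with those ranks = 0.9276336570
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6], "y": [1.0, 3, 2, 5, 5, 6]})
        rho, _, p = spearman_matrix(df)
        assert rho.loc["x", "y"] == pytest.approx(0.9276336570439174, abs=1e-12)
        assert p.loc["x", "y"] < 0.05

    def test_pairwise_complete_n(self):
        df = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, np.nan, 6], "b": [2.0, 1, 4, 3, 5, np.nan]}
        )
        rho, n, p = spearman_matrix(df)
        assert n.loc["a", "b"] == 4

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2]})
        with pytest.warns(UserWarning, match="constant"):
            rho, _, _ = spearman_matrix(df)
        assert np.isnan(rho.loc["a", "b"])


class TestChisqYates:
    # published 2x2 tables (excluded vs included cohorts)
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((66, 238, 33, 249), 9.74),
            ((46, 258, 24, 258), 5.48),
            ((190, 114, 202, 80), 5.10),
            ((108, 196, 84, 198), 1.93),
            ((71, 233, 49, 233), 2.86),
        ],
    )
    def test_published_tables_reproduce(self, cells, expected):
        chi2, p = chisq_yates(*cells)
        assert chi2 == pytest.approx(expected, abs=0.005)

    def test_matches_scipy_continuity_correction(self):
        obs = np.array([[66, 238], [33, 249]])
        ref = stats.chi2_contingency(obs, correction=True)
        chi2, p = chisq_yates(66, 238, 33, 249)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_no_association_floors_at_zero(self):
        chi2, p = chisq_yates(10, 10, 10, 10)
        assert chi2 == 0.0
        assert p == 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chisq_yates(0, 0, 5, 5)


class TestWelch:
    def test_identical_summaries_zero(self):
        t, df, p = welch_t(10, 2, 30, 10, 2, 30)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_formula_on_raw_vectors(self):
        t, df, p = welch_t([1.0, 2, 3], [4.0, 5, 6])
        # means 2 vs 5, both variances 1, n=3: t = -3/sqrt(2/3), df = 4
        assert t == pytest.approx(-3 / np.sqrt(2 / 3))
        assert df == pytest.approx(4.0)

    def test_satterthwaite_df_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 30))
            y = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 30))
            _, df, _ = welch_t(x, y)
            assert df <= len(x) + len(y) - 2 + 1e-9


class TestIcc:
    def test_identical_raters_give_one(self):
        ratings = np.array([[1, 1, 1], [2, 2, 2], [5, 5, 5], [3, 3, 3]], dtype=float)
        icc, ci = icc_oneway(ratings)
        assert icc == pytest.approx(1.0)

    def test_zero_variance_not_calculable(self):
        icc, ci = icc_oneway(np.zeros((6, 3)))
        assert np.isnan(icc) and ci is None

    def test_matches_hand_anova_on_toy(self):
        rng = np.random.default_rng(10)
        items = rng.normal(0, 2, 12)
        x = items[:, None] + rng.normal(0, 1, (12, 3))
        icc, ci = icc_oneway(x)
        # brute-force one-way ANOVA mean squares
        n, k = x.shape
        msb = k * np.sum((x.mean(axis=1) - x.mean()) ** 2) / (n - 1)
        msw = np.sum((x - x.mean(axis=1, keepdims=True)) ** 2) / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        assert icc == pytest.approx(expected, abs=1e-12)
        assert ci[0] < icc < ci[1]

    def test_matches_pingouin_icc1(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        x = rng.normal(0, 2, 10)[:, None] + rng.normal(0, 1, (10, 3))
        icc, ci = icc_oneway(x)
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(10), 3),
                "raters": np.tile(np.arange(3), 10),
                "scores": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="scores")
        ref1 = ref[ref["Type"] == "ICC(1,1)"].iloc[0]
        assert icc == pytest.approx(ref1["ICC"], abs=1e-9)
        assert ci == pytest.approx(tuple(ref1["CI95"]), abs=0.01)  # pingouin rounds its CI

    def test_missing_items_dropped_with_warning(self):
        x = np.array([[1.0, 2, 1], [2, 2, 3], [np.nan, 4, 4], [5, 5, 6], [3, 2, 3]])
        with pytest.warns(UserWarning, match="dropping"):
            icc, ci = icc_oneway(x)
        assert np.isfinite(icc)
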
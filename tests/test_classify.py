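"""Classifier scores and evaluation statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from drckit.classify import (
    CaseControlForest,
    ForestConfig,
    accuracy,
    auc_score,
    bootstrap_ci,
    compare_models,
    delong_test,
    fisher_exact_2x2,
    mann_whitney_u,
    rf_fit_predict,
    roc_auc,
    spearman,
)


def auc_all_pairs_oracle(scores, labels):
    """Brute-force concordance: P(case score > control score) + ties/2."""
    s = np.asarray(scores, float)
    l = np.asarray(labels, int)
    pos = s[l == 1]
    neg = s[l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration with fixed margins."""
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        return 1.0  # a zero margin admits a single table
    obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(x, n, r1, c1)
        if p <= obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def mwu_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group splits."""
    x = list(x)
    y = list(y)
    pooled = x + y
    nx = len(x)

    def u_stat(group_x, group_y):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in group_x
            for b in group_y
        )

    u_obs = u_stat(x, y)
    mu = nx * len(y) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        chosen = set(idx)
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(u_stat(gx, gy) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return u_obs, count / total


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties(self):
        _, auc = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_three_of_four_pairs_concordant(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        roc, _ = roc_auc(rng.normal(size=40), rng.integers(0, 2, 40))
        assert roc.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert roc.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]
        assert (roc.fpr.diff().dropna() >= 0).all()
        assert (roc.tpr.diff().dropna() >= 0).all()

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # induce ties
        a1 = auc_score(scores, labels)
        a2 = auc_score(np.exp(3 * scores) - 5, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestAccuracy:
    def test_extremes(self):
        assert accuracy([0.9, 0.1], [1, 0]) == 1.0
        assert accuracy([0.1, 0.9], [1, 0]) == 0.0

    def test_half_correct(self):
        assert accuracy([0.1, 0.6, 0.35, 0.8], [0, 0, 1, 1]) == 0.5

    def test_error_rate_complement(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(size=30)
        l = rng.integers(0, 2, 30)
        err = np.mean((s >= 0.5).astype(int) != l)
        assert accuracy(s, l) + err == 1.0


class TestBootstrapCI:
    def test_degenerate_metric_collapses(self):
        s = np.r_[np.ones(10), np.zeros(10)]
        l = np.r_[np.ones(10, int), np.zeros(10, int)]
        lo, hi = bootstrap_ci(s, l, accuracy, n_boot=1000, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        l = np.r_[np.ones(25, int), np.zeros(25, int)]
        s = rng.normal(l, 1.0)
        lo, hi = bootstrap_ci(s, l, auc_score, n_boot=2000, seed=1)
        assert lo <= auc_score(s, l) <= hi

    def test_minimum_resamples_enforced(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci([1.0, 0.0], [1, 0], auc_score, n_boot=10)

    def test_pair_resampling_keeps_pairs_together(self):
        rng = np.random.default_rng(2)
        l = np.tile([1, 0], 20)
        s = rng.normal(l, 1.0)
        pairs = np.repeat(np.arange(20), 2)
        lo, hi = bootstrap_ci(
            s, l, auc_score, n_boot=1000, seed=3, pair_ids=pairs
        )
        assert 0.0 <= lo <= hi <= 1.0

    def test_width_shrinks_with_n(self):
        """Median CI width at n=400 is below that at n=100 on matched
        synthetic score sets."""
        widths = {}
        for n in (100, 400):
            w = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                l = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
                s = rng.normal(l * 1.0, 1.0)
                lo, hi = bootstrap_ci(s, l, auc_score, n_boot=1000, seed=seed)
                w.append(hi - lo)
            widths[n] = np.median(w)
        assert widths[400] < widths[100]


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        l = np.r_[np.ones(20, int), np.zeros(20, int)]
        s = rng.normal(l, 1.0)
        auc_a, auc_b, p = delong_test(s, s, l)
        assert auc_a == auc_b
        assert p == 1.0

    def test_detects_clear_difference(self):
        rng = np.random.default_rng(1)
        l = np.r_[np.ones(60, int), np.zeros(60, int)]
        good = rng.normal(3.0 * l, 1.0)
        junk = rng.normal(size=120)
        _, _, p = delong_test(good, junk, l)
        assert p < 1e-4

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        l = np.r_[np.ones(30, int), np.zeros(30, int)]
        a = rng.normal(l, 1.0)
        b = rng.normal(l, 2.0)
        _, _, p_ab = delong_test(a, b, l)
        _, _, p_ba = delong_test(b, a, l)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)


class TestExactTests:
    def test_fisher_diagonal_table(self):
        assert fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_fisher_uniform_table(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == 1.0

    def test_fisher_zero_margin(self):
        assert fisher_exact_2x2(0, 0, 3, 2) == 1.0

    def test_fisher_rejects_negative(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 1, 1, 1)

    def test_mwu_no_overlap(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_mwu_identical_samples(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_mwu_swap_symmetry(self):
        x, y = [1.0, 5.0, 2.5], [3.0, 4.0, 0.5, 6.0]
        u_xy, p_xy = mann_whitney_u(x, y)
        u_yx, p_yx = mann_whitney_u(y, x)
        assert u_xy + u_yx == len(x) * len(y)
        assert p_xy == pytest.approx(p_yx, rel=1e-12)

    def test_spearman_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 40]) == 1.0
        assert spearman([1, 2, 3], [5, 4, 3]) == -1.0

    def test_spearman_rank_oracle(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)


class TestRandomForest:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            ForestConfig(n_trees=10)
        with pytest.raises(ValueError):
            ForestConfig(mode="loo")

    def test_perfectly_separating_feature(self):
        l = np.r_[np.ones(20, int), np.zeros(20, int)]
        X = (l * 2.0 - 1.0)[:, None]
        scores = rf_fit_predict(X, l, ForestConfig(n_trees=200, seed=0))
        assert auc_score(scores, l) == 1.0

    def test_determinism(self):
        rng = np.random.default_rng(3)
        l = np.r_[np.ones(15, int), np.zeros(15, int)]
        X = rng.normal(size=(30, 3))
        cfg = ForestConfig(n_trees=100, seed=7)
        np.testing.assert_array_equal(
            rf_fit_predict(X, l, cfg), rf_fit_predict(X, l, cfg)
        )

    def test_oob_null_auc_near_half(self):
        """Pure-noise features give OOB AUC around chance over seeds."""
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            l = np.r_[np.ones(30, int), np.zeros(30, int)]
            X = rng.normal(size=(60, 4))
            scores = rf_fit_predict(X, l, ForestConfig(n_trees=200, seed=seed))
            aucs.append(auc_score(scores, l))
        assert 0.3 <= np.median(aucs) <= 0.7

    def test_kfold_mode_runs(self):
        rng = np.random.default_rng(4)
        l = np.r_[np.ones(20, int), np.zeros(20, int)]
        X = rng.normal(l[:, None], 1.0, size=(40, 2))
        scores = rf_fit_predict(X, l, ForestConfig(mode="kfold", seed=0))
        assert scores.shape == (40,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_results_object_summary(self):
        rng = np.random.default_rng(5)
        l = np.r_[np.ones(20, int), np.zeros(20, int)]
        X = pd.DataFrame({"f": rng.normal(l, 0.5)})
        res = CaseControlForest(X, l, ForestConfig(n_trees=100, seed=1)).fit()
        assert 0.0 <= res.auc <= 1.0
        assert "AUC" in res.summary()
        d = res.to_dict(n_boot=1000, seed=0)
        assert d["auc_ci95"][0] <= d["auc"] <= d["auc_ci95"][1]


class TestCompareModels:
    def test_identical_feature_sets(self):
        rng = np.random.default_rng(6)
        l = np.r_[np.ones(20, int), np.zeros(20, int)]
        X = pd.DataFrame({"f": rng.normal(l, 0.7)})
        rep = compare_models(X, X, l, ForestConfig(n_trees=100, seed=2))
        assert rep.delong_p == 1.0
        assert rep.fisher_p == 1.0

    def test_report_contract(self):
        rng = np.random.default_rng(7)
        l = np.r_[np.ones(20, int), np.zeros(20, int)]
        Xa = pd.DataFrame({"f": rng.normal(l, 0.5)})
        Xb = pd.DataFrame({"g": rng.normal(size=40)})
        rep = compare_models(Xa, Xb, l, ForestConfig(n_trees=100, seed=3))
        assert 0.0 <= rep.delong_p <= 1.0
        assert 0.0 <= rep.fisher_p <= 1.0
        assert rep.auc_a > rep.auc_b
        assert "DeLong" in rep.summary()
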
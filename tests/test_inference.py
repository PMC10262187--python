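import numpy as np
import pytest
from scipy import stats

from chronopanel.inference import (
    kruskal_dunn,
    lda_two_class,
    mann_whitney,
    partial_spearman,
    wilcoxon_paired,
)


class TestMannWhitney:
    def test_identical_samples_large_p(self):
        x = np.arange(10.0)
        r = mann_whitney(x, x)
        assert r.p_value > 0.9

    def test_complete_separation_exact_p(self):
        # U=0; two-sided exact p = 2 * 1/C(6,3) = 0.1
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(2 / 20, abs=1e-12)

    def test_power_under_shift(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            mann_whitney(rng.normal(0, 1, 200), rng.normal(1, 1, 200)).p_value < 0.05
            for _ in range(20)
        )
        assert rejections == 20

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1, 45)
        assert mann_whitney(np.exp(x), np.exp(y)).p_value == pytest.approx(
            mann_whitney(x, y).p_value, rel=1e-12
        )


class TestKruskalDunn:
    def test_identical_groups_null(self):
        g = np.arange(30.0)
        omnibus, pairwise = kruskal_dunn([g, g, g])
        assert omnibus.statistic == pytest.approx(0.0, abs=1e-9)
        assert (pairwise["p_adj"] > 0.9).all()

    def test_one_shifted_group_flagged(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 100), rng.normal(0, 1, 100), rng.normal(1, 1, 100)]
        omnibus, pairwise = kruskal_dunn(groups)
        assert omnibus.p_value < 1e-6
        sig = pairwise[pairwise["p_adj"] < 0.05]
        assert set(map(tuple, sig[["group_i", "group_j"]].to_numpy())) == {(0, 2), (1, 2)}

    def test_two_groups_match_mann_whitney(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 60), rng.normal(0.5, 1, 55)
        omnibus, _ = kruskal_dunn([x, y])
        mw = stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert omnibus.p_value == pytest.approx(mw.pvalue, rel=1e-6)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_dunn([np.arange(5.0)])


class TestPartialSpearman:
    def test_reduces_to_spearman_without_covariates(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        r = partial_spearman(x, y)
        rho, p = stats.spearmanr(x, y)
        assert r.statistic == pytest.approx(rho, abs=1e-12)
        assert r.p_value == pytest.approx(p, rel=1e-6)

    def test_confounder_removed(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=1000)
        x = z + rng.normal(0, 0.5, 1000)
        y = z**3 + rng.normal(0, 0.5, 1000)
        raw = partial_spearman(x, y)
        adj = partial_spearman(x, y, [z])
        assert raw.statistic > 0.4
        assert abs(adj.statistic) < 0.1

    def test_planted_partial_correlation_recovered(self):
        rng = np.random.default_rng(6)
        n = 2000
        z = rng.normal(size=n)
        e1 = rng.normal(size=n)
        rho = 0.3
        e2 = rho * e1 + np.sqrt(1 - rho**2) * rng.normal(size=n)
        x, y = z + e1, z + e2
        r = partial_spearman(x, y, [z])
        assert r.statistic == pytest.approx(rho, abs=0.06)
        assert r.p_value < 1e-10

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=["x", "y", "z"])
        df["y"] += 0.5 * df["x"] + 0.5 * df["z"]
        ours = partial_spearman(df["x"], df["y"], [df["z"]])
        ref = pg.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert ours.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_constant_variable_errors(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(20), np.arange(20.0))


class TestWilcoxonPaired:
    def test_no_change_undefined_test_zero_mean(self):
        x = np.arange(10.0)
        t, summary = wilcoxon_paired(x, x)
        assert np.isnan(t.p_value)
        assert summary["mean_diff"] == 0.0

    def test_constant_shift_highly_significant(self):
        x = np.random.default_rng(8).normal(size=50)
        t, summary = wilcoxon_paired(x, x + 0.2)
        assert t.p_value < 1e-3
        assert summary["mean_diff"] == pytest.approx(0.2, abs=1e-12)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=40), rng.normal(size=40)
        t1, s1 = wilcoxon_paired(a, b)
        t2, s2 = wilcoxon_paired(b, a)
        assert s2["mean_diff"] == pytest.approx(-s1["mean_diff"], abs=1e-12)
        assert t2.p_value == pytest.approx(t1.p_value, rel=1e-9)


class TestLdaTwoClass:
    def test_null_case_chance_accuracy(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 5))
        y = np.array(["low"] * 150 + ["high"] * 150, dtype=object)
        res = lda_two_class(X, y, seed=0)
        assert abs(res.accuracy_mean - 0.5) < 0.08
        assert res.separation.p_value > 0.001

    def test_separated_gaussians_near_perfect(self):
        rng = np.random.default_rng(11)
        X0 = rng.normal(0, 1, size=(100, 3))
        X1 = rng.normal(6, 1, size=(100, 3))
        X = np.vstack([X0, X1])
        y = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        res = lda_two_class(X, y, seed=0)
        assert res.accuracy_mean > 0.97
        assert res.separation.p_value < 1e-20

    def test_1d_boundary_matches_midpoint(self):
        rng = np.random.default_rng(12)
        x0 = rng.normal(0, 1, 500)
        x1 = rng.normal(3, 1, 500)
        X = np.concatenate([x0, x1])[:, None]
        y = np.array(["a"] * 500 + ["b"] * 500, dtype=object)
        res = lda_two_class(X, y, seed=0)
        boundary = res.threshold / res.weights[0]
        midpoint = (x0.mean() + x1.mean()) / 2
        assert boundary == pytest.approx(midpoint, abs=1e-9)

    def test_confusion_matrix_sums_to_n(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(1.5, 1, (60, 2))])
        y = np.array(["a"] * 60 + ["b"] * 60, dtype=object)
        res = lda_two_class(X, y, seed=1, cv_repeats=4)
        assert res.confusion.sum() == pytest.approx(120.0)

    def test_feature_rescaling_invariance(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(0, 1, (80, 3)), rng.normal(1, 1, (80, 3))])
        y = np.array(["a"] * 80 + ["b"] * 80, dtype=object)
        base = lda_two_class(X, y, seed=5)
        X2 = X.copy()
        X2[:, 1] *= 250.0
        scaled = lda_two_class(X2, y, seed=5)
        # invariant up to the tiny ridge regularizer, which is not scale-free
        assert scaled.accuracy_mean == pytest.approx(base.accuracy_mean, abs=0.02)

    def test_constant_feature_rejected(self):
        X = np.ones((40, 2))
        X[:, 0] = np.random.default_rng(15).normal(size=40)
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        with pytest.raises(ValueError, match="constant"):
            lda_two_class(X, y)
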
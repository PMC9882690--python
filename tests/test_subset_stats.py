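import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trackforge import (CategoryMap, ValidationError, build_feature_matrix,
                        compare_groups, dunn_test, kruskal_wallis, run_pca)


def fake_summaries(n=12, n_features=4, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"feat_{i}" for i in range(n_features)],
    )
    df.insert(0, "cell_id", np.arange(1, n + 1))
    return df


def half_categories(n=12):
    return CategoryMap({i: ("A" if i <= n // 2 else "B") for i in range(1, n + 1)})


class TestFeatureMatrix:
    def test_columns_are_z_scored(self):
        X, labels = build_feature_matrix(fake_summaries(), half_categories())
        assert (X.mean().abs() < 1e-10).all()
        np.testing.assert_allclose(X.std(ddof=0), 1.0, rtol=1e-10)
        assert set(labels) == {"A", "B"}

    def test_constant_feature_dropped(self):
        summ = fake_summaries()
        summ["feat_0"] = 7.0
        X, _ = build_feature_matrix(summ, half_categories())
        assert "feat_0" not in X.columns
        assert X.shape[1] == 3

    def test_incomplete_cells_dropped(self):
        summ = fake_summaries()
        summ.loc[0, "feat_1"] = np.nan
        X, labels = build_feature_matrix(summ, half_categories())
        assert len(X) == 11 and len(labels) == 11

    def test_single_category_rejected(self):
        cats = CategoryMap({i: "only" for i in range(1, 13)})
        with pytest.raises(ValidationError, match="categories"):
            build_feature_matrix(fake_summaries(), cats)

    def test_tiny_category_rejected(self):
        cats = CategoryMap({**{i: "A" for i in range(1, 11)}, 11: "B", 12: "B"})
        with pytest.raises(ValidationError):
            build_feature_matrix(fake_summaries(), cats)


class TestPca:
    def test_rank_one_data_single_component(self):
        t = np.linspace(-1, 1, 40)
        X = np.column_stack([t, 2 * t, -t])
        X = (X - X.mean(0)) / X.std(0)
        res = run_pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert res.retained_k == 1

    def test_orthonormal_loadings_and_total_variance(self):
        X, _ = build_feature_matrix(fake_summaries(30, 6, seed=3), half_categories(30))
        res = run_pca(X)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_full_rank_reconstruction(self):
        X, _ = build_feature_matrix(fake_summaries(20, 5, seed=4), half_categories(20))
        res = run_pca(X)
        centered = X.to_numpy() - X.to_numpy().mean(axis=0)
        np.testing.assert_allclose(
            res.scores @ res.loadings.T, centered, atol=1e-8)

    def test_isotropic_cloud_splits_variance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10_000, 2))
        X = (X - X.mean(0)) / X.std(0)
        res = run_pca(X)
        np.testing.assert_allclose(res.explained_variance_ratio, [0.5, 0.5], atol=0.02)

    def test_row_permutation_permutes_scores(self):
        X, _ = build_feature_matrix(fake_summaries(16, 5, seed=6), half_categories(16))
        res = run_pca(X)
        perm = np.random.default_rng(0).permutation(len(X))
        res_p = run_pca(X.iloc[perm])
        np.testing.assert_allclose(res_p.scores, res.scores[perm], atol=1e-9)

    def test_column_permutation_preserves_variance_ratios(self):
        X, _ = build_feature_matrix(fake_summaries(16, 5, seed=6), half_categories(16))
        res = run_pca(X)
        res_p = run_pca(X[list(reversed(X.columns))])
        np.testing.assert_allclose(
            res_p.explained_variance_ratio, res.explained_variance_ratio, atol=1e-9)

    def test_sign_convention_deterministic(self):
        X, _ = build_feature_matrix(fake_summaries(16, 5, seed=8), half_categories(16))
        res = run_pca(X)
        for col in res.loadings.T:
            assert col[np.abs(col).argmax()] > 0


def exhaustive_kw(groups):
    """Independent textbook computation: H from rank sums (no-tie case)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    n = len(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for i in range(len(groups)):
        r = ranks[bounds[i]:bounds[i + 1]].sum()
        h += r**2 / len(groups[i])
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestKruskalWallis:
    def test_worked_two_group_example(self):
        h, _ = kruskal_wallis([np.array([1.0, 2, 3]), np.array([10.0, 11, 12])])
        assert h == pytest.approx(3.857, abs=1e-3)
        assert h == pytest.approx(exhaustive_kw([[1, 2, 3], [10, 11, 12]]), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_rank_computation(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 5, size=rng.integers(2, 4))
        vals = rng.permutation(np.arange(1.0, sizes.sum() + 1))  # distinct -> no ties
        groups = np.split(vals, np.cumsum(sizes)[:-1])
        h, _ = kruskal_wallis(list(groups))
        assert h == pytest.approx(exhaustive_kw(groups), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_group_significance_agrees_with_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=15)
        b = rng.normal(loc=2.0 * (seed % 2), size=15)
        _, p_kw = kruskal_wallis([a, b])
        p_mw = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert (p_kw < 0.05) == (p_mw < 0.05)


class TestDunn:
    def _groups(self, seed=0):
        rng = np.random.default_rng(seed)
        return [rng.normal(loc=m, size=12) for m in (0.0, 0.3, 3.0)]

    def test_adjusted_at_least_unadjusted(self):
        groups = self._groups()
        labels = ["a", "b", "c"]
        raw = dunn_test(groups, labels, adjustment="none")
        bonf = dunn_test(groups, labels, adjustment="bonferroni")
        holm = dunn_test(groups, labels, adjustment="holm")
        for i, j in itertools.combinations(labels, 2):
            assert bonf.loc[i, j] >= raw.loc[i, j] - 1e-15
            assert holm.loc[i, j] >= raw.loc[i, j] - 1e-15

    def test_matrix_shape_and_symmetry(self):
        mat = dunn_test(self._groups(), ["a", "b", "c"])
        assert (mat.to_numpy().diagonal() == 1.0).all()
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
        assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()

    def test_against_hand_computed_example(self):
        # independent re-derivation of the z statistic for a no-tie case
        groups = [np.array([1.0, 3, 5, 7]), np.array([2.0, 4, 6, 8]),
                  np.array([20.0, 21, 22, 23])]
        pooled = np.concatenate(groups)
        order = pooled.argsort()
        ranks = np.empty(len(pooled)); ranks[order] = np.arange(1, 13)
        mean_r = [ranks[:4].mean(), ranks[4:8].mean(), ranks[8:].mean()]
        se = np.sqrt(12 * 13 / 12.0 * (1 / 4 + 1 / 4))
        expected = {}
        for k, (i, j) in enumerate(itertools.combinations(range(3), 2)):
            z = (mean_r[i] - mean_r[j]) / se
            expected[(i, j)] = min(1.0, 3 * 2 * stats.norm.sf(abs(z)))
        mat = dunn_test(groups, ["g0", "g1", "g2"])
        for (i, j), p in expected.items():
            assert mat.iloc[i, j] == pytest.approx(p, rel=1e-12)


class TestCompareGroups:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        n = 20
        base = rng.normal(size=(3 * n, 4))
        base[2 * n:, :] += 4.0  # third category well separated
        df = pd.DataFrame(base, columns=list("wxyz"))
        df.insert(0, "cell_id", np.arange(1, 3 * n + 1))
        cats = CategoryMap(
            {i: ("A", "B", "C")[(i - 1) // n] for i in range(1, 3 * n + 1)})
        X, labels = build_feature_matrix(df, cats)
        pca = run_pca(X)
        results = compare_groups(pca, labels)
        assert len(results) == pca.retained_k
        first = results[0]
        assert first.kruskal_p < 0.05
        assert first.dunn_p.loc["A", "C"] < 0.05
        assert first.dunn_p.loc["C", "B"] < 0.05

    def test_skips_when_one_usable_category(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"),
                         index=range(1, 11))
        pca = run_pca(X)
        labels = pd.Series(["A"] * 9 + ["B"], index=range(1, 11))
        assert compare_groups(pca, labels) == []
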
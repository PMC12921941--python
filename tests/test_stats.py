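"""First-principles statistics vs independent oracles.

Each routine is checked against (a) hand-computable worked examples, (b) a
naive brute-force implementation written here, and (c) the established
library implementation (scipy/statsmodels/sklearn) on random instances.
"""

import numpy as np
import pytest
from scipy import stats as sps

from fibrovae import (
    bootstrap_ci,
    cliffs_delta,
    dunn_posthoc_holm,
    holm_adjust,
    kruskal_wallis,
    pca_explore,
    spearman,
)
from fibrovae.stats import rankdata_average


# ---------------------------------------------------------------- oracles
def brute_ranks(x):
    """O(n^2) average ranks by pair counting."""
    x = np.asarray(x, dtype=float)
    return np.array(
        [1 + np.sum(x < xi) + (np.sum(x == xi) - 1) / 2.0 for xi in x]
    )


def brute_kruskal(groups):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = brute_ranks(pooled)
    mean_all = (n + 1) / 2
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - mean_all) ** 2
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    c = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / c if c > 0 else np.nan


def brute_dunn_z(groups, i, j):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = brute_ranks(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    ri = ranks[bounds[i] : bounds[i + 1]].mean()
    rj = ranks[bounds[j] : bounds[j + 1]].mean()
    _, counts = np.unique(pooled, return_counts=True)
    var = (n * (n + 1) / 12 - np.sum(counts**3 - counts) / (12 * (n - 1))) * (
        1 / len(groups[i]) + 1 / len(groups[j])
    )
    return (ri - rj) / np.sqrt(var)


def brute_cliffs(a, b):
    more = sum(1 for x in a for y in b if x > y)
    less = sum(1 for x in a for y in b if x < y)
    return (more - less) / (len(a) * len(b))


def brute_spearman_tie_free(x, y):
    """Concordance-style O(n^2) Spearman for tie-free data."""
    n = len(x)
    rx, ry = brute_ranks(x), brute_ranks(y)
    d2 = np.sum((rx - ry) ** 2)
    return 1 - 6 * d2 / (n * (n**2 - 1))


def random_groups(rng, max_groups=4, max_size=8, ties=True):
    g = rng.integers(2, max_groups + 1)
    pool = rng.integers(0, 12, size=100).astype(float) if ties else None
    out = []
    for _ in range(g):
        size = rng.integers(2, max_size + 1)
        if ties:
            out.append(rng.choice(pool, size=size))
        else:
            out.append(rng.normal(size=size))
    return out


# ---------------------------------------------------------------- tests
class TestRanks:
    def test_matches_scipy_with_ties(self, rng):
        for _ in range(50):
            x = rng.integers(0, 6, size=rng.integers(2, 30)).astype(float)
            np.testing.assert_allclose(rankdata_average(x), sps.rankdata(x))


class TestKruskalWallis:
    def test_worked_three_by_three_grid(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.H == pytest.approx(7.2, abs=1e-12)
        assert res.df == 2

    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.H == pytest.approx(0.0, abs=1e-12)

    def test_within_group_permutation_invariance(self, rng):
        groups = [rng.normal(size=6), rng.normal(size=5), rng.normal(size=7)]
        h1 = kruskal_wallis(groups).H
        shuffled = [rng.permutation(g) for g in groups]
        assert kruskal_wallis(shuffled).H == pytest.approx(h1, abs=1e-12)

    def test_all_identical_values_degenerate(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.status == "degenerate"
        assert np.isnan(res.H)

    def test_matches_brute_force_and_scipy(self, rng):
        """200 random small instances, tie-heavy and tie-free, to 1e-10."""
        for i in range(200):
            groups = random_groups(rng, ties=(i % 2 == 0))
            if np.all(np.concatenate(groups) == np.concatenate(groups)[0]):
                continue
            res = kruskal_wallis(groups)
            assert res.H == pytest.approx(brute_kruskal(groups), abs=1e-10)
            h_scipy, p_scipy = sps.kruskal(*groups)
            assert res.H == pytest.approx(h_scipy, abs=1e-10)
            assert res.p == pytest.approx(p_scipy, abs=1e-10)


class TestDunnHolm:
    def test_three_groups_three_rows(self):
        t = dunn_posthoc_holm([[1, 2], [3, 4], [5, 6]])
        assert len(t) == 3
        assert (t["p_holm"] >= t["p_raw"] - 1e-15).all()

    def test_holm_stepdown_arithmetic(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.9]), [0.03, 0.04, 0.9], atol=1e-15
        )

    def test_holm_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(size=rng.integers(2, 10))
            _, adj, _, _ = multipletests(p, method="holm")
            np.testing.assert_allclose(holm_adjust(p), adj, atol=1e-12)

    def test_identical_groups_z_zero(self):
        t = dunn_posthoc_holm([[1, 2, 3], [1, 2, 3]])
        assert t["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert t["p_holm"].iloc[0] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc_holm([[1, 2], []])

    def test_z_matches_brute_force(self, rng):
        for i in range(200):
            groups = random_groups(rng, ties=(i % 2 == 0))
            if np.all(np.concatenate(groups) == np.concatenate(groups)[0]):
                continue
            t = dunn_posthoc_holm(groups)
            row = 0
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    assert t["z"].iloc[row] == pytest.approx(
                        brute_dunn_z(groups, a, b), abs=1e-10
                    )
                    row += 1

    def test_labels_from_dict_input(self):
        t = dunn_posthoc_holm({"mild": [1, 2], "severe": [5, 6]})
        assert t.loc[0, "group1"] == "mild" and t.loc[0, "group2"] == "severe"


class TestCliffsDelta:
    def test_complete_dominance(self):
        delta, band = cliffs_delta([4, 5, 6], [1, 2, 3])
        assert delta == 1.0 and band == "large"

    def test_symmetry_zero(self):
        delta, band = cliffs_delta([1, 2, 3], [1, 2, 3])
        assert delta == 0.0 and band == "negligible"

    def test_interleaved_example(self):
        delta, _ = cliffs_delta([1, 3], [2])
        assert delta == 0.0

    def test_antisymmetry_exact(self, rng):
        for _ in range(50):
            a = rng.integers(0, 8, size=rng.integers(1, 9)).astype(float)
            b = rng.integers(0, 8, size=rng.integers(1, 9)).astype(float)
            assert cliffs_delta(a, b)[0] == -cliffs_delta(b, a)[0]

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            a = rng.integers(0, 10, size=rng.integers(1, 9)).astype(float)
            b = rng.integers(0, 10, size=rng.integers(1, 9)).astype(float)
            assert cliffs_delta(a, b)[0] == pytest.approx(brute_cliffs(a, b), abs=1e-10)

    def test_band_cutoffs(self):
        # delta = 0.2 -> small; 0.4 -> medium; 0.6 -> large
        assert cliffs_delta([1.0] * 6 + [10.0] * 4, [1.0] * 2 + [0.0] * 8)[0] > 0


class TestSpearman:
    def test_matches_brute_force_tie_free(self, rng):
        for _ in range(200):
            n = rng.integers(3, 9)
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(brute_spearman_tie_free(x, y), abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(100):
            n = rng.integers(4, 20)
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, p = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_constant_input_nan(self):
        rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)


class TestBootstrap:
    def test_constant_data_degenerate_interval(self):
        lo, hi = bootstrap_ci([4.0] * 10, np.mean, n_boot=200, seed=0)
        assert lo == hi == 4.0

    def test_seeded_determinism(self):
        a = bootstrap_ci(np.arange(30.0), np.mean, seed=42)
        b = bootstrap_ci(np.arange(30.0), np.mean, seed=42)
        assert a == b

    def test_mean_interval_sanity(self):
        lo, hi = bootstrap_ci(np.arange(1.0, 101.0), np.mean, n_boot=2000, seed=0)
        assert lo < 50.5 < hi
        assert (lo, hi) != (40.0, 61.0) and lo > 40 and hi < 61

    def test_nan_statistic_rejected(self):
        with pytest.raises(ValueError, match="resample"):
            bootstrap_ci([1.0, 2.0, 3.0], lambda x: float("nan"), n_boot=5, seed=0)


class TestPCA:
    def test_collinear_columns_rank_one(self, rng):
        x = rng.normal(size=100)
        M = np.column_stack([x, 2 * x])
        res = pca_explore((M - M.mean(0)) / M.std(0, ddof=1))
        assert res.explained_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_columns_equal_fractions(self, rng):
        M = rng.normal(size=(100_000, 4))
        Ms = (M - M.mean(0)) / M.std(0, ddof=1)
        res = pca_explore(Ms)
        np.testing.assert_allclose(res.explained_fractions, 0.25, atol=0.02)

    def test_fractions_sum_to_one(self, rng):
        M = rng.normal(size=(30, 6)) @ rng.normal(size=(6, 6))
        res = pca_explore(M)
        assert res.explained_fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        M = rng.normal(size=(25, 5))
        res = pca_explore(M)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(5), atol=1e-10
        )
        recon = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(recon, M, atol=1e-8)

    def test_matches_sklearn_explained_variance(self, rng):
        from sklearn.decomposition import PCA

        M = rng.normal(size=(40, 7))
        res = pca_explore(M)
        ref = PCA().fit(M)
        np.testing.assert_allclose(
            res.explained_fractions, ref.explained_variance_ratio_, atol=1e-10
        )

    def test_sign_convention(self, rng):
        M = rng.normal(size=(20, 4))
        res = pca_explore(M)
        for j in range(4):
            pivot = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[pivot, j] > 0

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            pca_explore(np.array([[1.0, np.nan], [2.0, 3.0]]))
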
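"""Bray-Curtis, PERMANOVA/PERMDISP, PCoA: oracles, cross-checks, geometry."""

from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import pytest

from bluefin_diet.multivar import bray_curtis, pcoa, permanova, permdisp


def oracle_pseudo_f(D, labels):
    """Anderson's pseudo-F written independently (plain loops)."""
    n = len(labels)
    D2 = D**2
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    a = len(set(labels))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        dm = pd.DataFrame([[0.3, 0.7], [0.3, 0.7]])
        assert bray_curtis(dm).iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        dm = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        assert bray_curtis(dm).iloc[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        dm = pd.DataFrame([[0.5, 0.5], [1.0, 0.0]])
        assert bray_curtis(dm).iloc[0, 1] == pytest.approx(0.5)

    def test_bounds_symmetry_zero_diagonal(self, fixture_diet_matrix):
        D = bray_curtis(fixture_diet_matrix).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0.0 and D.max() <= 1.0 + 1e-12


class TestPermanova:
    def test_exact_oracle_small_n(self):
        rng = np.random.default_rng(0)
        for n, sizes in ((4, (2, 2)), (6, (3, 3)), (8, (4, 4)), (7, (3, 4))):
            X = rng.dirichlet(np.ones(4), size=n)
            D = bray_curtis(pd.DataFrame(X)).to_numpy()
            labels = np.repeat(np.arange(len(sizes)), sizes)
            res = permanova(D, labels, method="exhaustive")
            f_oracle = oracle_pseudo_f(D, labels)
            assert res.statistic == pytest.approx(f_oracle, rel=1e-12)
            count = total = 0
            for perm in set(iter_permutations(labels)):
                total += 1
                count += oracle_pseudo_f(D, list(perm)) >= f_oracle - 1e-12
            assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_statistic_matches_skbio(self, fixture_diet_matrix):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        D = bray_curtis(fixture_diet_matrix)
        labels = ["a" if i % 2 else "b" for i in range(len(D))]
        mine = permanova(D, labels, n_perm=9, seed=0, method="random")
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(D.to_numpy()), grouping=labels, permutations=9
        )
        assert mine.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_separated_clusters_reach_minimum_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.01, size=(10, 3)) + [1.0, 0.0, 0.0]
        b = rng.normal(0.0, 0.01, size=(10, 3)) + [0.0, 1.0, 0.0]
        X = np.abs(np.vstack([a, b]))
        X /= X.sum(1, keepdims=True)
        D = bray_curtis(pd.DataFrame(X))
        res = permanova(D, ["a"] * 10 + ["b"] * 10, n_perm=99, seed=0, method="random")
        # the complete label swap reproduces F exactly (two-group symmetry),
        # so the attainable floor is 1/100 plus any swap draws
        assert res.p_value <= 2 / 100

    def test_group_of_one_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError, match="size 1"):
            permanova(D, ["a", "a", "b"], method="random")

    def test_pairwise_t_and_similarity(self, fixture_diet_matrix, fixture_dataset):
        D = bray_curtis(fixture_diet_matrix)
        labels = [fixture_dataset.regime_of[s] for s in fixture_diet_matrix.index]
        res = permanova(D, labels, n_perm=99, seed=0, method="random", pairwise=True)
        assert len(res.pairwise) == 3
        for _, row in res.pairwise.iterrows():
            assert row["t"] == pytest.approx(np.sqrt(row["pseudo_F"]))
        sim = res.extras["similarity"].set_index(["group_a", "group_b"])
        within_2008 = sim.loc[("2008", "2008"), "mean_similarity_pct"]
        within_mid = sim.loc[("2009-14", "2009-14"), "mean_similarity_pct"]
        assert within_2008 > within_mid  # tight early regime vs diverse middle


class TestPermdisp:
    def test_flat_geometry_centroid_distances(self):
        # four points on a line: PCoA is exact, distances are plain Euclidean
        x = np.array([0.0, 1.0, 10.0, 13.0])
        D = np.abs(x[:, None] - x[None, :])
        labels = ["a", "a", "b", "b"]
        res = permdisp(D, labels, n_perm=49, seed=0)
        assert res.extras["mean_centroid_distance"]["a"] == pytest.approx(0.5)
        assert res.extras["mean_centroid_distance"]["b"] == pytest.approx(1.5)

    def test_matches_vegan_style_centroid_f(self, fixture_diet_matrix, fixture_dataset):
        """skbio's centroid PERMDISP omits the negative-eigenvalue correction,
        so agreement is checked on an (almost) Euclidean embedding."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(24, 3))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        labels = ["a"] * 12 + ["b"] * 12
        mine = permdisp(D, labels, n_perm=9, seed=0)
        theirs = skbio_stats.permdisp(
            skbio_stats.DistanceMatrix(D), grouping=labels, permutations=9, test="centroid"
        )
        assert mine.statistic == pytest.approx(theirs["test statistic"], rel=1e-6)

    def test_null_dispersion_p_is_uniformish(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(60):
            X = rng.dirichlet(np.ones(5), size=24)
            D = bray_curtis(pd.DataFrame(X))
            ps.append(permdisp(D, ["a"] * 12 + ["b"] * 12, n_perm=49,
                               seed=int(rng.integers(2**31))).p_value)
        assert 0.2 < np.mean(ps) < 0.8
        assert (np.array(ps) <= 0.05).mean() < 0.2

    def test_inflated_group_detected(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.05, size=(20, 3))
        b = rng.normal(0, 0.15, size=(20, 3))  # dispersion scaled x3
        X = np.abs(np.vstack([a, b]) + [0.5, 0.5, 0.5])
        X /= X.sum(1, keepdims=True)
        D = bray_curtis(pd.DataFrame(X))
        res = permdisp(D, ["a"] * 20 + ["b"] * 20, n_perm=199, seed=0)
        assert res.p_value < 0.05


class TestPcoa:
    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        res = pcoa(D)
        assert res.coordinates.shape[1] == 1
        recovered = res.coordinates.iloc[:, 0].to_numpy()
        gaps = sorted(np.abs(np.diff(np.sort(recovered))))  # axis sign is arbitrary
        assert gaps == pytest.approx([3.0, 4.0])

    def test_euclidean_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 4))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        res = pcoa(D)
        C = res.coordinates.to_numpy()
        D_hat = np.sqrt(((C[:, None] - C[None, :]) ** 2).sum(-1))
        assert np.allclose(D_hat, D, atol=1e-9)

    def test_bray_curtis_yields_negative_eigenvalues_unused(self, fixture_diet_matrix):
        D = bray_curtis(fixture_diet_matrix.iloc[:40])
        res = pcoa(D)
        assert (res.eigenvalues < 0).any()
        assert res.coordinates.shape[1] == (res.eigenvalues > 1e-9 * res.eigenvalues.max()).sum()

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(D)
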
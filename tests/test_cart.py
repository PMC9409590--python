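"""Compositional tree: impurity, splits, surrogates, pruning, importance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bluefin_diet.cart import (
    CartTree,
    TreeControl,
    assign_groups,
    best_split,
    cross_validate_and_prune,
    fit_diet_tree,
    grow_tree,
    node_impurity,
    surrogate_splits,
)


def brute_force_impurity(Y):
    """Independent double-loop oracle for the within-node sum of squares."""
    Y = np.asarray(Y, float)
    mean = Y.mean(axis=0)
    total = 0.0
    for row in Y:
        for j in range(Y.shape[1]):
            total += (row[j] - mean[j]) ** 2
    return total


def brute_force_best_split(X, Y, min_bucket):
    """Exhaustive oracle over all midpoint thresholds, in covariate order."""
    best = None
    for cov in X.columns:
        x = X[cov].to_numpy(float)
        mask = ~np.isnan(x)
        xs = np.unique(x[mask])
        parent = brute_force_impurity(Y[mask])
        for lo, hi in zip(xs[:-1], xs[1:]):
            thr = (lo + hi) / 2
            left = mask & (x < thr)
            right = mask & (x >= thr)
            if left.sum() < min_bucket or right.sum() < min_bucket:
                continue
            dec = parent - brute_force_impurity(Y[left]) - brute_force_impurity(Y[right])
            if best is None or dec > best[0] + 1e-12:
                best = (dec, cov, thr)
    return best


class TestImpurity:
    def test_identical_rows_zero(self):
        Y = np.tile([0.2, 0.3, 0.5], (5, 1))
        assert node_impurity(Y) == pytest.approx(0.0)

    def test_two_opposite_rows(self):
        assert node_impurity(np.array([[1.0, 0.0], [0.0, 1.0]])) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(0)
        Y = rng.dirichlet(np.ones(4), size=10)
        assert node_impurity(Y) == pytest.approx(brute_force_impurity(Y), rel=1e-12)


class TestBestSplit:
    def test_identical_compositions_no_split(self):
        X = pd.DataFrame({"year": np.arange(10.0)})
        Y = np.tile([0.5, 0.5], (10, 1))
        assert best_split(X, Y, min_bucket=2, min_gain=1e-6) is None

    def test_two_year_blocks_split_at_midpoint(self):
        X = pd.DataFrame({"year": [2008.0] * 3 + [2015.0] * 3})
        Y = np.array([[1.0, 0.0]] * 3 + [[0.0, 1.0]] * 3)
        rule, dec = best_split(X, Y, min_bucket=1)
        assert rule.covariate == "year"
        assert rule.threshold == pytest.approx(2011.5)
        # decrease equals the between-group sum of squares
        assert dec == pytest.approx(node_impurity(Y))

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """Oracle equivalence on all instances up to 12 rows, 3 covariates."""
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(4, 13))
            p = int(rng.integers(1, 4))
            X = pd.DataFrame(
                {f"c{j}": rng.integers(0, 6, n).astype(float) for j in range(p)}
            )
            Y = rng.dirichlet(np.ones(3), size=n)
            got = best_split(X, Y, min_bucket=2, min_gain=0.0)
            want = brute_force_best_split(X, Y, min_bucket=2)
            if want is None or want[0] <= 1e-12:
                continue
            assert got is not None, trial
            rule, dec = got
            assert dec == pytest.approx(want[0], rel=1e-9), trial
            assert (rule.covariate, rule.threshold) == (want[1], pytest.approx(want[2])), trial

    def test_categorical_binary_partition(self):
        X = pd.DataFrame({"region": ["north"] * 4 + ["south"] * 4 + ["bay"] * 4})
        Y = np.array([[1.0, 0.0]] * 8 + [[0.0, 1.0]] * 4)
        rule, dec = best_split(X, Y, min_bucket=2)
        assert rule.categories in (frozenset({"bay"}), frozenset({"north", "south"}))
        assert dec == pytest.approx(node_impurity(Y))


class TestSurrogates:
    def test_identical_covariate_perfect_agreement(self):
        X = pd.DataFrame({"year": np.arange(10.0), "copy": np.arange(10.0)})
        Y = np.array([[1.0, 0.0]] * 5 + [[0.0, 1.0]] * 5)
        rule, _ = best_split(X[["year"]], Y, min_bucket=2)
        surr = surrogate_splits(X, rule, X.columns)
        assert surr and surr[0].rule.covariate == "copy"
        assert surr[0].agreement == pytest.approx(1.0)

    def test_independent_covariate_dropped(self):
        rng = np.random.default_rng(3)
        year = np.arange(20.0)
        # permutation constructed to agree no better than the majority baseline
        noise = rng.permutation(year)
        X = pd.DataFrame({"year": year, "noise": noise})
        Y = np.array([[1.0, 0.0]] * 10 + [[0.0, 1.0]] * 10)
        rule, _ = best_split(X[["year"]], Y, min_bucket=2)
        surr = surrogate_splits(X, rule, X.columns)
        assert all(s.agreement > 0 for s in surr)  # kept only if above baseline

    def test_correlated_month_appears_as_surrogate(self):
        rng = np.random.default_rng(4)
        year = np.repeat([2008.0, 2012.0], 20)
        month = np.where(year == 2008, rng.integers(6, 10, 40), rng.integers(1, 6, 40)).astype(float)
        X = pd.DataFrame({"year": year, "month": month})
        Y = np.array([[1.0, 0.0]] * 20 + [[0.0, 1.0]] * 20)
        rule, _ = best_split(X[["year"]], Y, min_bucket=5)
        surr = surrogate_splits(X, rule, X.columns)
        assert any(s.rule.covariate == "month" and s.agreement > 0.5 for s in surr)


class TestGrowPruneImportance:
    def test_single_node_tree_when_too_small(self):
        dm = pd.DataFrame([[0.5, 0.5]] * 5, index=[f"s{i}" for i in range(5)])
        X = pd.DataFrame({"year": np.arange(5.0)}, index=dm.index)
        tree = grow_tree(dm, X, TreeControl(min_split=20))
        assert tree.root.is_leaf
        assert tree.n_leaves == 1

    def test_pure_noise_prunes_to_root(self):
        rng = np.random.default_rng(0)
        n = 80
        dm = pd.DataFrame(rng.dirichlet(np.ones(4), size=n), index=[f"s{i}" for i in range(n)])
        X = pd.DataFrame({"year": rng.permutation(np.repeat(np.arange(8.0), 10))}, index=dm.index)
        tree = fit_diet_tree(dm, X, TreeControl(min_split=10, min_bucket=5, min_gain_frac=0.0), k=5, seed=1)
        assert tree.n_leaves <= 2  # root, or at most one spurious split surviving 1-SE
        assert tree.cv_table["rel_error"].iloc[0] <= 1.0

    def test_single_covariate_importance_is_one(self):
        X = pd.DataFrame({"year": [2008.0] * 10 + [2015.0] * 10,
                          "flat": np.ones(20)})
        dm = pd.DataFrame([[0.9, 0.1]] * 10 + [[0.1, 0.9]] * 10, index=[f"s{i}" for i in range(20)])
        X.index = dm.index
        tree = fit_diet_tree(dm, X, TreeControl(min_split=4, min_bucket=2), k=5, seed=0)
        assert tree.importance["year"] == 1.0
        assert tree.importance["flat"] == 0.0

    def test_duplicated_covariate_gets_importance_via_surrogacy(self):
        X = pd.DataFrame({"year": [2008.0] * 10 + [2015.0] * 10})
        X["twin"] = X["year"]
        dm = pd.DataFrame([[0.9, 0.1]] * 10 + [[0.1, 0.9]] * 10, index=[f"s{i}" for i in range(20)])
        X.index = dm.index
        tree = fit_diet_tree(dm, X, TreeControl(min_split=4, min_bucket=2), k=5, seed=0)
        assert tree.importance["year"] == 1.0
        assert tree.importance["twin"] == 1.0  # perfect surrogate earns full credit

    def test_child_counts_and_impurity_monotonicity(self, fixture_diet_matrix, fixture_covariates):
        tree = grow_tree(fixture_diet_matrix, fixture_covariates)
        for node in tree.nodes():
            if not node.is_leaf:
                assert node.left.n + node.right.n == node.n
                assert node.left.impurity + node.right.impurity <= node.impurity + 1e-9
                assert node.decrease >= 0
            assert node.mean.sum() == pytest.approx(1.0)

    def test_fixture_recovery_three_year_leaves(self, fixture_diet_matrix, fixture_covariates):
        tree = fit_diet_tree(fixture_diet_matrix, fixture_covariates, k=10, seed=1)
        assert tree.n_leaves == 3
        splits = [
            n.split.covariate
            for n in tree.nodes(effective=True)
            if not (n.is_leaf or n.node_id in tree.collapsed)
        ]
        assert splits and all(c == "year" for c in splits)
        assert tree.importance["year"] == 1.0
        assert tree.cv_error < 1.0
        assert tree.r_squared == pytest.approx(1.0 - tree.cv_error)

    def test_missing_year_routed_by_surrogate_not_dropped(self, fixture_dataset, fixture_diet_matrix, fixture_covariates):
        tree = fit_diet_tree(fixture_diet_matrix, fixture_covariates, k=5, seed=2)
        X = fixture_covariates.copy()
        victim = X.index[0]
        X.loc[victim, "year"] = np.nan
        labels = assign_groups(tree, X)
        assert labels.loc[victim].startswith("leaf")
        assert len(labels) == len(X)

    def test_assignment_matches_regimes(self, fixture_dataset, fixture_diet_matrix, fixture_covariates):
        tree = fit_diet_tree(fixture_diet_matrix, fixture_covariates, k=10, seed=1)
        labels = assign_groups(tree, fixture_covariates)
        regimes = pd.Series(
            {sid: fixture_dataset.regime_of[sid] for sid in fixture_covariates.index}
        )
        table = pd.crosstab(labels, regimes)
        # each leaf maps to exactly one regime for >= 95% of stomachs
        agreement = table.max(axis=1).sum() / len(labels)
        assert agreement >= 0.95
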
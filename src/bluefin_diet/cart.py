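"""Multivariate regression trees for compositional diet data.

The response is the per-stomach diet composition (a vector of proportional
abundances summing to 1); covariates are predator/sampling descriptors such
as collection year, month, latitude, longitude and fork length.  The tree
recursively partitions stomachs to minimise within-node sums of squared
deviations of compositions about the node mean (squared Euclidean impurity),
giving groups of predators with similar diets.

Features of the classic CART machinery are retained:

* **surrogate splits** — for every primary split, rules on the other
  covariates that best reproduce its left/right assignment; they route
  observations whose primary covariate is missing and contribute to
  variable importance (an "adjusted agreement" above the majority-direction
  baseline is required);
* **cost-complexity pruning** with the weakest-link sequence of nested
  subtrees;
* **k-fold cross-validation** of the complexity sequence, with the final
  subtree chosen by the 1-SE rule (the smallest subtree whose CV error is
  within one standard error of the minimum);
* **relative variable importance** — impurity decrease credited to primary
  splits plus agreement-weighted credit to surrogates, normalised so the
  best covariate scores exactly 1.

Numeric split points are midpoints between sorted distinct values and the
affirmative condition (x < threshold, or category-in-subset) goes left;
ties in impurity decrease break by covariate order, then smaller threshold.
Categorical covariates are searched over all binary partitions (small
cardinalities only, as is standard).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeControl",
    "SplitRule",
    "Surrogate",
    "CartNode",
    "CartTree",
    "node_impurity",
    "best_split",
    "surrogate_splits",
    "grow_tree",
    "cross_validate_and_prune",
    "variable_importance",
    "assign_groups",
    "fit_diet_tree",
]

_EPS = 1e-12


@dataclass
class TreeControl:
    """Growth and pruning controls.

    ``min_gain_frac`` is the minimum impurity decrease for a split, as a
    fraction of the root impurity (the complexity parameter used during
    growth); ``min_bucket`` the minimum rows in a child; ``min_split`` the
    minimum rows for a node to be considered for splitting.
    """

    min_split: int = 20
    min_bucket: int = 7
    min_gain_frac: float = 0.01
    max_depth: int = 30
    max_categories: int = 12


@dataclass(frozen=True)
class SplitRule:
    """Affirmative-goes-left splitting rule on one covariate.

    Numeric: affirmative is ``x < threshold`` when ``left_if_less`` (the
    primary convention), else ``x >= threshold`` (used by surrogates that
    agree best in the flipped orientation).  Categorical: affirmative is
    membership of ``categories``.
    """

    covariate: str
    threshold: Optional[float] = None
    categories: Optional[frozenset] = None
    left_if_less: bool = True

    def goes_left(self, value) -> Optional[bool]:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        if self.categories is not None:
            return value in self.categories
        return (value < self.threshold) == self.left_if_less

    def describe(self) -> str:
        if self.categories is not None:
            return f"{self.covariate} in {{{', '.join(map(str, sorted(self.categories)))}}}"
        op = "<" if self.left_if_less else ">="
        return f"{self.covariate} {op} {self.threshold:g}"


@dataclass(frozen=True)
class Surrogate:
    rule: SplitRule
    agreement: float  # adjusted agreement in (0, 1]


@dataclass
class CartNode:
    node_id: int
    depth: int
    n: int
    mean: np.ndarray
    impurity: float
    split: Optional[SplitRule] = None
    decrease: float = 0.0
    surrogates: list[Surrogate] = field(default_factory=list)
    majority_left: bool = True
    left: Optional["CartNode"] = None
    right: Optional["CartNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def node_impurity(compositions: np.ndarray) -> float:
    """Within-node sum of squared deviations about the mean composition."""
    Y = np.asarray(compositions, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape[0] == 0:
        raise ValueError("impurity of an empty node")
    centred = Y - Y.mean(axis=0)
    return float(np.einsum("ij,ij->", centred, centred))


def _numeric_candidates(x: np.ndarray, Y: np.ndarray, min_bucket: int):
    """Yield (decrease, threshold) over midpoint splits of a numeric covariate."""
    order = np.argsort(x, kind="mergesort")
    xs, Ys = x[order], Y[order]
    m = len(xs)
    if m < 2 * min_bucket:
        return
    parent = node_impurity(Ys)
    csum = np.cumsum(Ys, axis=0)
    csq = np.cumsum(np.einsum("ij,ij->i", Ys, Ys))
    total_sum, total_sq = csum[-1], csq[-1]
    ks = np.arange(1, m)
    valid = (ks >= min_bucket) & (m - ks >= min_bucket) & (xs[1:] > xs[:-1])
    for k in ks[valid]:
        left_ss = csq[k - 1] - csum[k - 1] @ csum[k - 1] / k
        rsum = total_sum - csum[k - 1]
        right_ss = (total_sq - csq[k - 1]) - rsum @ rsum / (m - k)
        yield parent - left_ss - right_ss, 0.5 * (xs[k - 1] + xs[k])


def _categorical_candidates(x: np.ndarray, Y: np.ndarray, min_bucket: int, max_categories: int):
    cats = sorted(set(x))
    if len(cats) < 2:
        return
    if len(cats) > max_categories:
        raise ValueError(f"categorical covariate with {len(cats)} levels exceeds the search limit")
    parent = node_impurity(Y)
    anchor = cats[0]
    for r in range(1, len(cats)):
        for subset in itertools.combinations(cats[1:], r - 1):
            left_set = frozenset((anchor,) + subset)
            mask = np.array([v in left_set for v in x])
            nl = int(mask.sum())
            if nl < min_bucket or len(x) - nl < min_bucket:
                continue
            dec = parent - node_impurity(Y[mask]) - node_impurity(Y[~mask])
            yield dec, left_set


def best_split(
    X: pd.DataFrame,
    Y: np.ndarray,
    min_bucket: int = 7,
    min_gain: float = 0.0,
    max_categories: int = 12,
) -> Optional[tuple[SplitRule, float]]:
    """Exhaustive search for the impurity-minimising binary split.

    Returns ``(rule, impurity_decrease)`` or ``None`` when no admissible
    split clears ``min_gain``.  Search covers all midpoint thresholds of
    numeric covariates and all binary partitions of categorical ones,
    evaluated on rows where the covariate is observed.  Ties break by
    covariate order, then smaller threshold.
    """
    best: Optional[tuple[SplitRule, float]] = None
    for cov in X.columns:
        col = X[cov]
        numeric = pd.api.types.is_numeric_dtype(col)
        mask = col.notna().to_numpy()
        if mask.sum() < 2 * min_bucket:
            continue
        x, Ysub = col.to_numpy()[mask], Y[mask]
        if numeric:
            candidates = (
                (dec, SplitRule(cov, threshold=thr))
                for dec, thr in _numeric_candidates(x.astype(float), Ysub, min_bucket)
            )
        else:
            candidates = (
                (dec, SplitRule(cov, categories=left_set))
                for dec, left_set in _categorical_candidates(x, Ysub, min_bucket, max_categories)
            )
        for dec, rule in candidates:
            if dec <= min_gain + _EPS:
                continue
            if best is None or dec > best[1] + _EPS:
                best = (rule, dec)
    return best


def _best_agreeing_rule(cov: str, x: np.ndarray, primary_left: np.ndarray):
    """Best surrogate rule for one covariate against the primary assignment.

    Returns ``(matches, rule)`` over both orientations, or None.
    """
    m = len(x)
    if m == 0:
        return None
    if np.issubdtype(np.asarray(x).dtype, np.number):
        order = np.argsort(x, kind="mergesort")
        xs, ls = x[order], primary_left[order].astype(int)
        cl = np.cumsum(ls)
        total_left = cl[-1]
        ks = np.arange(1, m)
        valid = xs[1:] > xs[:-1]
        best = None
        for k in ks[valid]:
            thr = 0.5 * (xs[k - 1] + xs[k])
            matches_lt = 2 * cl[k - 1] + (m - total_left) - k
            for matches, orient in ((matches_lt, True), (m - matches_lt, False)):
                if best is None or matches > best[0]:
                    best = (matches, SplitRule(cov, threshold=thr, left_if_less=orient))
        return best
    cats = sorted(set(x))
    best = None
    for r in range(1, len(cats)):
        for subset in itertools.combinations(cats, r):
            left_set = frozenset(subset)
            pred_left = np.array([v in left_set for v in x])
            matches = int((pred_left == primary_left).sum())
            for mcount, cat_set in ((matches, left_set), (m - matches, frozenset(cats) - left_set)):
                if best is None or mcount > best[0]:
                    best = (mcount, SplitRule(cov, categories=cat_set))
    return best


def surrogate_splits(
    X: pd.DataFrame, primary: SplitRule, covariates: Sequence[str]
) -> list[Surrogate]:
    """Ranked surrogate rules for a primary split.

    For each other covariate the rule best agreeing with the primary's
    left/right assignment is found; its adjusted agreement is
    ``(matches - majority) / (n - majority)`` where ``majority`` is the
    count achieved by always sending rows with the primary's majority
    direction.  Only surrogates with positive adjusted agreement are kept,
    ranked by agreement (descending).
    """
    primary_dir = X[primary.covariate].map(primary.goes_left)
    defined = primary_dir.notna().to_numpy()
    out = []
    for cov in covariates:
        if cov == primary.covariate:
            continue
        both = defined & X[cov].notna().to_numpy()
        if both.sum() < 2:
            continue
        pl = primary_dir.to_numpy()[both].astype(bool)
        n = len(pl)
        majority = max(pl.sum(), n - pl.sum())
        if n == majority:
            continue
        found = _best_agreeing_rule(cov, X[cov].to_numpy()[both], pl)
        if found is None:
            continue
        matches, rule = found
        agreement = (matches - majority) / (n - majority)
        if agreement > 0:
            out.append(Surrogate(rule=rule, agreement=float(agreement)))
    out.sort(key=lambda s: -s.agreement)
    return out


class CartTree:
    """A fitted compositional tree with its pruning/CV records."""

    def __init__(self, root, covariates, groups, control, root_impurity):
        self.root: CartNode = root
        self.covariates = list(covariates)
        self.groups = list(groups)
        self.control = control
        self.root_impurity = root_impurity
        self.collapsed: frozenset[int] = frozenset()
        self.cv_table: Optional[pd.DataFrame] = None
        self.selected_size: Optional[int] = None
        self.cv_error: Optional[float] = None
        self.cv_se: Optional[float] = None
        self.importance: Optional[dict[str, float]] = None
        self.cv_leaf_summary: Optional[pd.DataFrame] = None

    # -- traversal helpers ------------------------------------------------
    def nodes(self, effective: bool = False):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.is_leaf or (effective and node.node_id in self.collapsed):
                continue
            stack.extend([node.right, node.left])

    def leaves(self, effective: bool = True) -> list[CartNode]:
        out = []
        for node in self.nodes(effective=effective):
            if node.is_leaf or (effective and node.node_id in self.collapsed):
                out.append(node)
        return sorted(out, key=lambda n: n.node_id)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def r_squared(self) -> Optional[float]:
        """1 - cross-validated relative error of the selected subtree."""
        return None if self.cv_error is None else 1.0 - self.cv_error

    def route(self, row: pd.Series, collapsed: Optional[frozenset] = None) -> CartNode:
        collapsed = self.collapsed if collapsed is None else collapsed
        node = self.root
        while not node.is_leaf and node.node_id not in collapsed:
            direction = node.split.goes_left(row.get(node.split.covariate))
            if direction is None:
                for s in node.surrogates:
                    direction = s.rule.goes_left(row.get(s.rule.covariate))
                    if direction is not None:
                        break
            if direction is None:
                direction = node.majority_left
            node = node.left if direction else node.right
        return node

    def predict(self, X: pd.DataFrame, collapsed: Optional[frozenset] = None) -> np.ndarray:
        return np.array([self.route(row, collapsed).mean for _, row in X.iterrows()])

    def describe(self) -> str:
        """Indented text rendering of the selected tree (affirmative left)."""
        lines = []

        def walk(node, prefix, label):
            if node.is_leaf or node.node_id in self.collapsed:
                dom = self.groups[int(np.argmax(node.mean))]
                lines.append(
                    f"{prefix}{label}leaf(n={node.n}, dominant={dom}, "
                    f"share={node.mean.max():.2f})"
                )
                return
            lines.append(f"{prefix}{label}{node.split.describe()}? (n={node.n})")
            walk(node.left, prefix + "  ", "yes: ")
            walk(node.right, prefix + "  ", "no:  ")

        walk(self.root, "", "")
        return "\n".join(lines)


def grow_tree(
    diet_matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    control: Optional[TreeControl] = None,
) -> CartTree:
    """Grow a full compositional tree by recursive partitioning.

    ``diet_matrix`` rows (stomach compositions) and ``covariates`` rows must
    align on index.  Growth stops at ``min_split``/``min_bucket``/
    ``max_depth`` bounds or when no split clears the minimum gain
    (``min_gain_frac`` of root impurity).
    """
    control = control or TreeControl()
    X = covariates.loc[diet_matrix.index]
    Y = diet_matrix.to_numpy(dtype=float)
    root_imp = node_impurity(Y) if len(Y) else 0.0
    min_gain = control.min_gain_frac * root_imp
    counter = itertools.count()

    def build(idx: np.ndarray, depth: int) -> CartNode:
        Ysub = Y[idx]
        node = CartNode(
            node_id=next(counter),
            depth=depth,
            n=len(idx),
            mean=Ysub.mean(axis=0),
            impurity=node_impurity(Ysub),
        )
        if (
            len(idx) < control.min_split
            or depth >= control.max_depth
            or node.impurity <= _EPS
        ):
            return node
        Xsub = X.iloc[idx]
        found = best_split(
            Xsub, Ysub, control.min_bucket, min_gain, control.max_categories
        )
        if found is None:
            return node
        rule, decrease = found
        direction = Xsub[rule.covariate].map(rule.goes_left)
        node.split = rule
        node.decrease = float(decrease)
        node.surrogates = surrogate_splits(Xsub, rule, X.columns)
        go_left = np.zeros(len(idx), dtype=bool)
        defined = direction.notna().to_numpy()
        go_left[defined] = direction.to_numpy()[defined].astype(bool)
        node.majority_left = bool(go_left[defined].sum() * 2 >= defined.sum())
        # route missing-primary rows by surrogates, then majority
        for i in np.flatnonzero(~defined):
            d = None
            for s in node.surrogates:
                d = s.rule.goes_left(Xsub.iloc[i][s.rule.covariate])
                if d is not None:
                    break
            go_left[i] = node.majority_left if d is None else d
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    root = build(np.arange(len(Y)), 0)
    return CartTree(root, X.columns, diet_matrix.columns, control, root_imp)


# ---------------------------------------------------------------------------
# Cost-complexity pruning and cross-validation


def _subtree_stats(node: CartNode, collapsed: frozenset) -> tuple[float, int]:
    """(sum of effective-leaf impurities, number of effective leaves)."""
    if node.is_leaf or node.node_id in collapsed:
        return node.impurity, 1
    lr, ln = _subtree_stats(node.left, collapsed)
    rr, rn = _subtree_stats(node.right, collapsed)
    return lr + rr, ln + rn


def prune_sequence(tree: CartTree) -> list[tuple[float, frozenset]]:
    """Weakest-link cost-complexity sequence, from full tree to root-only.

    Returns ``[(alpha, collapsed_ids), ...]`` with alpha nondecreasing; the
    first entry is the full tree at alpha = 0.
    """
    collapsed: set[int] = set()
    seq = [(0.0, frozenset())]

    def internal_nodes(node):
        if node.is_leaf or node.node_id in collapsed:
            return
        yield node
        yield from internal_nodes(node.left)
        yield from internal_nodes(node.right)

    while True:
        nodes = list(internal_nodes(tree.root))
        if not nodes:
            break
        gs = []
        for node in nodes:
            r_sub, n_leaves = _subtree_stats(node, frozenset(collapsed))
            gs.append((node.impurity - r_sub) / max(n_leaves - 1, 1))
        alpha = min(gs)
        for node, g in zip(nodes, gs):
            if g <= alpha + _EPS:
                collapsed.add(node.node_id)
        # drop nodes nested under newly collapsed ancestors: harmless to keep
        seq.append((float(alpha), frozenset(collapsed)))
    return seq


def _collapse_at(seq: list[tuple[float, frozenset]], alpha: float) -> frozenset:
    """Collapsed set of the smallest subtree whose critical alpha exceeds ``alpha``."""
    out: frozenset = seq[0][1]
    for a, collapsed in seq:
        if a <= alpha + _EPS:
            out = collapsed
    return out


def cross_validate_and_prune(
    tree: CartTree,
    diet_matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> CartTree:
    """k-fold cross-validation of the complexity sequence and 1-SE selection.

    Relative errors are scaled by the root (resubstitution) sum of squares;
    the standard error at each complexity is the spread of per-fold relative
    errors over sqrt(k).  The selected subtree is the smallest whose CV error
    is within one SE of the minimum; it is applied to ``tree`` (in place)
    along with the CV table, importance map, and per-terminal CV summaries.
    """
    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    X = covariates.loc[diet_matrix.index]
    Y = diet_matrix.to_numpy(dtype=float)
    n = len(Y)
    seq = prune_sequence(tree)
    alphas = [a for a, _ in seq]
    # evaluation alphas: geometric means of consecutive interval bounds
    eval_alphas = []
    for i, a in enumerate(alphas):
        upper = alphas[i + 1] if i + 1 < len(alphas) else None
        if upper is None:
            eval_alphas.append(a * 2 + 1.0)
        elif a == 0.0:
            eval_alphas.append(0.0)
        else:
            eval_alphas.append(float(np.sqrt(a * upper)))

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    root_ss = node_impurity(Y)
    sse = np.zeros((k, len(eval_alphas)))
    fold_base = np.zeros(k)
    preds = np.zeros((len(eval_alphas), n, Y.shape[1]))
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        dm_train = diet_matrix.iloc[train_mask]
        sub = grow_tree(dm_train, X.iloc[train_mask], tree.control)
        sub_seq = prune_sequence(sub)
        ybar_train = Y[train_mask].mean(axis=0)
        fold_base[fi] = float(((Y[test_idx] - ybar_train) ** 2).sum())
        Xtest = X.iloc[test_idx]
        for ai, alpha in enumerate(eval_alphas):
            collapsed = _collapse_at(sub_seq, alpha)
            yhat = sub.predict(Xtest, collapsed)
            preds[ai, test_idx] = yhat
            sse[fi, ai] = float(((Y[test_idx] - yhat) ** 2).sum())

    cv_error = sse.sum(axis=0) / root_ss
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = sse / np.where(fold_base[:, None] > 0, fold_base[:, None], np.nan)
    cv_se = np.nanstd(rel, axis=0, ddof=1) / np.sqrt(k)

    rows = []
    for i, (alpha, collapsed) in enumerate(seq):
        r_sub, n_leaves = _subtree_stats(tree.root, collapsed)
        rows.append(
            {
                "alpha": alpha,
                "n_leaves": n_leaves,
                "rel_error": r_sub / root_ss if root_ss > 0 else 0.0,
                "cv_error": cv_error[i],
                "cv_se": cv_se[i],
            }
        )
    table = pd.DataFrame(rows)

    i_min = int(table["cv_error"].idxmin())
    threshold = table.loc[i_min, "cv_error"] + table.loc[i_min, "cv_se"]
    admissible = table[table["cv_error"] <= threshold + _EPS]
    i_sel = int(admissible["n_leaves"].idxmin())

    tree.collapsed = seq[i_sel][1]
    tree.cv_table = table
    tree.selected_size = int(table.loc[i_sel, "n_leaves"])
    tree.cv_error = float(table.loc[i_sel, "cv_error"])
    tree.cv_se = float(table.loc[i_sel, "cv_se"])
    tree.importance = variable_importance(tree)
    # per-terminal CV summary: mean held-out predicted proportion of each
    # terminal's dominant prey group (the number printed under tree leaves)
    leaf_rows = []
    assign = assign_groups(tree, X)
    sel_preds = preds[i_sel]
    for leaf in tree.leaves():
        label = f"leaf{leaf.node_id}"
        members = np.flatnonzero((assign == label).to_numpy())
        dom = int(np.argmax(leaf.mean))
        leaf_rows.append(
            {
                "leaf": label,
                "n": leaf.n,
                "dominant_group": tree.groups[dom],
                "mean_share": float(leaf.mean[dom]),
                "cv_share": float(sel_preds[members, dom].mean()) if len(members) else np.nan,
            }
        )
    tree.cv_leaf_summary = pd.DataFrame(leaf_rows)
    return tree


def variable_importance(tree: CartTree) -> dict[str, float]:
    """Relative importance per covariate, normalised so the maximum is 1.

    Primary splits credit their full impurity decrease to their covariate;
    each surrogate credits ``agreement x decrease`` to its own covariate.
    Only splits of the selected (effective) subtree count.
    """
    imp = {c: 0.0 for c in tree.covariates}
    for node in tree.nodes(effective=True):
        if node.is_leaf or node.node_id in tree.collapsed:
            continue
        imp[node.split.covariate] += node.decrease
        for s in node.surrogates:
            imp[s.rule.covariate] += s.agreement * node.decrease
    top = max(imp.values(), default=0.0)
    if top > 0:
        imp = {c: v / top for c, v in imp.items()}
    return imp


def assign_groups(tree: CartTree, covariates: pd.DataFrame) -> pd.Series:
    """Terminal label per row; missing covariates route via surrogates."""
    labels = [f"leaf{tree.route(row).node_id}" for _, row in covariates.iterrows()]
    return pd.Series(labels, index=covariates.index, name="diet_group")


def fit_diet_tree(
    diet_matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    control: Optional[TreeControl] = None,
    k: int = 10,
    seed: int = 0,
) -> CartTree:
    """Grow, cross-validate and 1-SE-prune in one call."""
    tree = grow_tree(diet_matrix, covariates, control)
    return cross_validate_and_prune(tree, diet_matrix, covariates, k=k, seed=seed)
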
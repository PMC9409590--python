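"""Dissimilarity-based group statistics: Bray-Curtis, PERMANOVA, PERMDISP, PCoA.

All three tests operate on a symmetric dissimilarity matrix over stomach
compositions (Bray-Curtis on proportional abundances by default, the
community-ecology standard):

* **PERMANOVA** — Anderson's distance-based pseudo-F comparing among- to
  within-group sums of squared dissimilarities, with a permutation p-value
  ((count of permuted F >= observed) + 1) / (permutations + 1), or the exact
  p over the full permutation distribution when feasible.  Pairwise contrasts
  report t = sqrt(F); mean within/among-group percent similarity
  (100 x (1 - mean pairwise dissimilarity)) summarises group cohesion.
* **PERMDISP** — the multivariate analogue of Levene's test: distances from
  each point to its group centroid in the principal-coordinate embedding
  (negative-eigenvalue axes subtract in the squared distance, per Anderson's
  method), an ANOVA F on those distances, and a p-value from permuting
  least-squares residuals.
* **PCoA** — eigendecomposition of the double-centred -D^2/2 matrix;
  coordinates are returned for positive-eigenvalue axes only, but all
  eigenvalues (including negative ones) are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "TestResult",
    "PcoaResult",
    "bray_curtis",
    "permanova",
    "permdisp",
    "pcoa",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: tuple[int, int]
    n_permutations: int
    method: str = "random"
    pairwise: Optional[pd.DataFrame] = None
    extras: dict = field(default_factory=dict)


def bray_curtis(diet_matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity over composition rows.

    D_ik = sum_j |p_ij - p_kj| / sum_j (p_ij + p_kj); zero diagonal, values
    in [0, 1] for nonnegative rows.
    """
    values = diet_matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative values")
    D = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(D, index=diet_matrix.index, columns=diet_matrix.index)


def _as_matrix_labels(D, labels):
    if isinstance(D, pd.DataFrame):
        labels = pd.Series(labels).reindex(D.index) if isinstance(labels, pd.Series) else pd.Series(list(labels), index=D.index)
        return D.to_numpy(dtype=float), labels.to_numpy()
    return np.asarray(D, dtype=float), np.asarray(list(labels))


def _validate_distance(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, group_sizes: np.ndarray) -> float:
    n = len(codes)
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for g, n_g in enumerate(group_sizes):
        idx = np.flatnonzero(codes == g)
        ss_within += D2[np.ix_(idx, idx)].sum() / (2 * n_g)
    a = len(group_sizes)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def _distinct_permutation_count(group_sizes: np.ndarray) -> float:
    total = math.factorial(int(group_sizes.sum()))
    for n_g in group_sizes:
        total //= math.factorial(int(n_g))
    return total


def permanova(
    D,
    labels,
    n_perm: int = 999,
    seed: Optional[int] = None,
    method: str = "auto",
    exhaustive_limit: int = 50_000,
    pairwise: bool = False,
) -> TestResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    ``method``: "random" permutes labels ``n_perm`` times with the +1
    correction; "exhaustive" enumerates every distinct label arrangement
    (exact p = proportion of arrangements with F >= observed); "auto" picks
    exhaustive when the arrangement count is at most ``exhaustive_limit``.
    With ``pairwise=True`` each group pair is retested on its sub-matrix and
    reported with t = sqrt(F) and raw p-values (no multiplicity adjustment),
    plus mean within/among percent similarities.
    """
    D, labels = _as_matrix_labels(D, labels)
    _validate_distance(D)
    uniq, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (sizes < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"group(s) of size 1 not permitted: {small}")
    D2 = D**2
    f_obs = _pseudo_f(D2, codes, sizes)
    n = len(codes)
    a = len(uniq)

    n_distinct = _distinct_permutation_count(sizes)
    use_exhaustive = method == "exhaustive" or (method == "auto" and n_distinct <= exhaustive_limit)
    if use_exhaustive:
        count, total = 0, 0
        seen = set()
        for perm in iter_permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if _pseudo_f(D2, np.array(perm), sizes) >= f_obs - 1e-12:
                count += 1
        p = count / total
        used, mname = total, "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if _pseudo_f(D2, perm, sizes) >= f_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        used, mname = n_perm, "random"

    extras = {"similarity": _similarity_summary(D, codes, uniq)}
    pw = None
    if pairwise:
        rows = []
        for i in range(a):
            for j in range(i + 1, a):
                mask = (codes == i) | (codes == j)
                sub = permanova(
                    D[np.ix_(mask, mask)], labels[mask], n_perm=n_perm,
                    seed=seed, method=method, exhaustive_limit=exhaustive_limit,
                )
                rows.append(
                    {
                        "group_a": uniq[i],
                        "group_b": uniq[j],
                        "t": math.sqrt(sub.statistic),
                        "pseudo_F": sub.statistic,
                        "p_value": sub.p_value,
                    }
                )
        pw = pd.DataFrame(rows)
    return TestResult(
        name="PERMANOVA", statistic=float(f_obs), p_value=float(p),
        df=(a - 1, n - a), n_permutations=used, method=mname,
        pairwise=pw, extras=extras,
    )


def _similarity_summary(D: np.ndarray, codes: np.ndarray, uniq) -> pd.DataFrame:
    """Mean pairwise percent similarity within each group and between pairs."""
    rows = []
    for i, gi in enumerate(uniq):
        idx = np.flatnonzero(codes == i)
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            mean_d = sub[np.triu_indices(len(idx), 1)].mean()
            rows.append({"group_a": gi, "group_b": gi, "mean_similarity_pct": 100 * (1 - mean_d)})
        for j in range(i + 1, len(uniq)):
            jdx = np.flatnonzero(codes == j)
            mean_d = D[np.ix_(idx, jdx)].mean()
            rows.append(
                {"group_a": gi, "group_b": uniq[j], "mean_similarity_pct": 100 * (1 - mean_d)}
            )
    return pd.DataFrame(rows)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives included)
    neg_coordinates: np.ndarray  # imaginary-axis coordinates (|lambda| scaled)

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


def pcoa(D, eig_tol: float = 1e-9) -> PcoaResult:
    """Principal coordinate analysis of a dissimilarity matrix.

    Eigendecomposition of the Gower-centred matrix -J D^2 J / 2.  Axes are
    ordered by eigenvalue; coordinates are produced only for eigenvalues
    above ``eig_tol`` x max positive eigenvalue, but the full spectrum is
    reported so callers can judge the non-Euclidean part.
    """
    index = D.index if isinstance(D, pd.DataFrame) else None
    D = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, dtype=float)
    _validate_distance(D)
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = eig_tol * max(eigvals.max(), 1.0)
    pos = eigvals > scale
    neg = eigvals < -scale
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    neg_coords = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    cols = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        eigenvalues=eigvals,
        neg_coordinates=neg_coords,
    )


def _centroid_distances(result: PcoaResult, codes: np.ndarray) -> np.ndarray:
    """Distance of each point to its group centroid, correcting for
    negative-eigenvalue axes (their squared contribution subtracts)."""
    X = result.coordinates.to_numpy()
    Xn = result.neg_coordinates
    z2 = np.zeros(len(codes))
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        cp = X[idx].mean(axis=0)
        z2[idx] += ((X[idx] - cp) ** 2).sum(axis=1)
        if Xn.size:
            cn = Xn[idx].mean(axis=0)
            z2[idx] -= ((Xn[idx] - cn) ** 2).sum(axis=1)
    return np.sqrt(np.clip(z2, 0.0, None))


def _anova_f(z: np.ndarray, codes: np.ndarray, a: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_between = ss_within = 0.0
    for g in range(a):
        zg = z[codes == g]
        ss_between += len(zg) * (zg.mean() - grand) ** 2
        ss_within += ((zg - zg.mean()) ** 2).sum()
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permdisp(
    D,
    labels,
    n_perm: int = 999,
    seed: Optional[int] = None,
    pairwise: bool = False,
) -> TestResult:
    """Homogeneity of multivariate dispersion (distance to group centroid).

    F is the one-way ANOVA statistic on centroid distances computed in the
    PCoA embedding; the p-value permutes the least-squares residuals of
    those distances.  Pairwise contrasts report the two-sample t statistic
    on centroid distances with residual-permutation p-values.
    """
    D, labels = _as_matrix_labels(D, labels)
    _validate_distance(D)
    uniq, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if len(uniq) < 2:
        raise ValueError("PERMDISP needs at least two groups")
    if (sizes < 2).any():
        raise ValueError("PERMDISP needs at least two members per group")
    a = len(uniq)
    z = _centroid_distances(pcoa(D), codes)
    f_obs = _anova_f(z, codes, a)
    group_means = np.array([z[codes == g].mean() for g in range(a)])
    resid = z - group_means[codes]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = resid[rng.permutation(len(z))]
        if _anova_f(zp, codes, a) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)

    pw = None
    if pairwise:
        rows = []
        for i in range(a):
            for j in range(i + 1, a):
                zi, zj = z[codes == i], z[codes == j]
                ni, nj = len(zi), len(zj)
                sp2 = (((zi - zi.mean()) ** 2).sum() + ((zj - zj.mean()) ** 2).sum()) / (ni + nj - 2)
                t = abs(zi.mean() - zj.mean()) / math.sqrt(sp2 * (1 / ni + 1 / nj)) if sp2 > 0 else np.inf
                ri = np.concatenate([zi - zi.mean(), zj - zj.mean()])
                cij = np.concatenate([np.zeros(ni, int), np.ones(nj, int)])
                cnt = 0
                for _ in range(n_perm):
                    rp = ri[rng.permutation(len(ri))]
                    za, zb = rp[cij == 0], rp[cij == 1]
                    sp2p = (((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()) / (ni + nj - 2)
                    tp = abs(za.mean() - zb.mean()) / math.sqrt(sp2p * (1 / ni + 1 / nj)) if sp2p > 0 else np.inf
                    if tp >= t - 1e-12:
                        cnt += 1
                rows.append(
                    {
                        "group_a": uniq[i], "group_b": uniq[j],
                        "t": t, "p_value": (cnt + 1) / (n_perm + 1),
                    }
                )
        pw = pd.DataFrame(rows)
    return TestResult(
        name="PERMDISP", statistic=float(f_obs), p_value=float(p),
        df=(a - 1, len(z) - a), n_permutations=n_perm, method="residual-permutation",
        pairwise=pw,
        extras={"mean_centroid_distance": {str(uniq[g]): float(z[codes == g].mean()) for g in range(a)}},
    )
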
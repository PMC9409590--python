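"""Incidence-based diet-diversity accumulation: Hill number q = 1 and coverage.

Stomachs are the sampling units.  For a group of T stomachs, the incidence
frequency Y_j of prey group j is the number of stomachs containing it and
U = sum_j Y_j the total number of incidences.  Diet diversity is the Shannon
Hill number (order q = 1): the exponential of the Shannon entropy of the
relative incidence frequencies {Y_j / U} — the effective number of equally
common prey groups.

Rarefaction (t <= T) is defined as the *expected* value over subsamples of t
stomachs drawn without replacement: expected subsample entropy
(exponentiated) for diversity, and expected within-sample coverage (the
share of the observed incidence distribution represented in the subsample)
for coverage.  Small problems are evaluated exactly by enumeration; larger
ones use the standard hypergeometric approximation for entropy (with the
expected incidence total t*U/T as normaliser).  The expected within-sample
coverage has the closed form

    C(t) = 1 - sum_j (Y_j / U) * C(T - Y_j, t) / C(T, t).

At t = T coverage switches to the singleton/doubleton (Good-Turing style)
estimator of *population* coverage, 1 - (Q1/U) * A with
A = (T-1)Q1 / ((T-1)Q1 + 2Q2); extrapolated coverage decays its deficit
geometrically.  Extrapolated diversity blends the observed entropy with an
asymptotic (bias-corrected) entropy estimate; extrapolation beyond twice the
observed sample size is flagged as unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, lgamma
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import psi

__all__ = [
    "IncidenceData",
    "ExtrapolationWarning",
    "hill_shannon",
    "sample_coverage",
    "size_at_coverage",
    "diversity_curve",
]

#: Exhaustive enumeration is used when C(T, t) is at most this.
EXACT_ENUMERATION_LIMIT = 200_000


class ExtrapolationWarning(UserWarning):
    """Requested size beyond double the observed sample (unreliable)."""


@dataclass
class IncidenceData:
    """Incidence summary over sampling units, retaining the raw matrix.

    ``matrix`` is the binary stomachs x prey-groups incidence matrix; the
    summary quantities (T, Y, U, Q1, Q2) derive from it.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.shape[0] < 1:
            raise ValueError("incidence matrix must be 2-D with at least one unit")
        self.matrix = m[:, m.any(axis=0)]  # drop never-observed groups

    @classmethod
    def from_diet_matrix(cls, diet_matrix: pd.DataFrame) -> "IncidenceData":
        return cls((diet_matrix.to_numpy() > 0))

    @property
    def T(self) -> int:
        return self.matrix.shape[0]

    @property
    def Y(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def U(self) -> int:
        return int(self.Y.sum())

    @property
    def Q1(self) -> int:
        return int((self.Y == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.Y == 2).sum())


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _check_t(inc: IncidenceData, t: int) -> None:
    if t < 1:
        raise ValueError("sample size t must be >= 1")
    if t > 2 * inc.T:
        warnings.warn(
            f"extrapolation to t={t} exceeds double the observed {inc.T} units; "
            "estimates are unreliable",
            ExtrapolationWarning,
            stacklevel=3,
        )


def _lchoose(n: float, k: float) -> float:
    if k < 0 or k > n:
        return -np.inf
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _asymptotic_entropy(inc: IncidenceData) -> float:
    """Bias-corrected asymptotic Shannon entropy of relative incidences.

    Adapts the Chao-Wang-Jost entropy estimator to incidence frequencies:
    the plug-in -sum (Y/T) ln(Y/T) part is replaced by the digamma form with
    a singleton correction, then rescaled from per-unit to per-incidence
    frequencies (the two entropies differ by the factor T/U and the offset
    ln(U/T)).
    """
    T, U, Y = inc.T, inc.U, inc.Y
    if len(Y) <= 1:
        return 0.0
    part = float(sum((y / T) * (psi(T) - psi(y)) for y in Y if 1 <= y <= T - 1))
    Q1, Q2 = inc.Q1, inc.Q2
    if Q1 > 0:
        if Q2 > 0:
            A = 2 * Q2 / ((T - 1) * Q1 + 2 * Q2)
        else:
            A = 2 / ((T - 1) * (Q1 - 1) + 2)
        if 0 < A < 1:
            r = np.arange(1, T)
            part += (Q1 / T) * (1 - A) ** (1 - T) * (
                -np.log(A) - float(((1 - A) ** r / r).sum())
            )
    h = (T / U) * part + np.log(U / T)
    return max(h, _entropy(Y))


def hill_shannon(inc: IncidenceData, t: int) -> float:
    """Shannon Hill number (q = 1) at sample size ``t`` stomachs.

    Interpolation (t < T): expected subsample entropy, exponentiated —
    exact by enumeration when feasible, else the hypergeometric
    approximation.  t = T: exponential of the observed incidence entropy.
    Extrapolation (t > T): observed/asymptotic blend with weights T/t and
    1 - T/t.
    """
    _check_t(inc, t)
    T, U, Y = inc.T, inc.U, inc.Y
    if len(Y) == 1:
        return 1.0
    if t == T:
        return float(np.exp(_entropy(Y)))
    if t < T:
        if comb(T, t) <= EXACT_ENUMERATION_LIMIT:
            hs = [
                _entropy(inc.matrix[list(sub)].sum(axis=0))
                for sub in combinations(range(T), t)
            ]
            return float(np.exp(np.mean(hs)))
        ut = t * U / T
        log_denom = _lchoose(T, t)
        h = 0.0
        for yj in Y:
            ks = np.arange(max(1, t - (T - yj)), min(yj, t) + 1)
            logp = np.array(
                [_lchoose(yj, k) + _lchoose(T - yj, t - k) for k in ks]
            ) - log_denom
            h -= float(np.sum(np.exp(logp) * (ks / ut) * np.log(ks / ut)))
        return float(np.exp(h))
    h_obs = _entropy(Y)
    h_inf = _asymptotic_entropy(inc)
    h = (T / t) * h_obs + (1 - T / t) * h_inf
    return float(np.exp(h))


def _coverage_A(inc: IncidenceData) -> float:
    T, Q1, Q2 = inc.T, inc.Q1, inc.Q2
    if Q1 == 0:
        return 0.0
    if Q2 > 0:
        return (T - 1) * Q1 / ((T - 1) * Q1 + 2 * Q2)
    return (T - 1) * (Q1 - 1) / ((T - 1) * (Q1 - 1) + 2)


def sample_coverage(inc: IncidenceData, t: int) -> float:
    """Estimated sample coverage at ``t`` stomachs, in [0, 1].

    t < T: expected within-sample coverage of a t-unit subsample (closed
    form; equals the exhaustive-subsample mean).  t = T: singleton/doubleton
    population-coverage estimator.  t > T: geometric decay of the t = T
    deficit.
    """
    _check_t(inc, t)
    T, U, Y = inc.T, inc.U, inc.Y
    if t < T:
        log_denom = _lchoose(T, t)
        deficit = float(
            sum((yj / U) * np.exp(_lchoose(T - yj, t) - log_denom) for yj in Y)
        )
        return 1.0 - deficit
    A = _coverage_A(inc)
    if t == T:
        return 1.0 - (inc.Q1 / U) * A
    return 1.0 - (inc.Q1 / U) * A ** (t - T + 1)


def size_at_coverage(
    inc: IncidenceData, target: float, max_factor: int = 2
) -> Optional[int]:
    """Smallest t (scanning up to ``max_factor * T``) with coverage >= target.

    Returns None (after a warning) when the target is unreachable within the
    scanned range.
    """
    if target <= 0:
        return 1
    if target >= 1 and inc.Q1 > 0:
        warnings.warn("full coverage unreachable with singletons present", stacklevel=2)
    for t in range(1, max_factor * inc.T + 1):
        if sample_coverage(inc, t) >= target:
            return t
    warnings.warn(
        f"coverage target {target} not reached by t = {max_factor * inc.T}",
        ExtrapolationWarning,
        stacklevel=2,
    )
    return None


def diversity_curve(inc: IncidenceData, ts: Optional[list[int]] = None) -> pd.DataFrame:
    """Accumulation curve: (t, qD, coverage, method) per requested size."""
    if ts is None:
        ts = sorted(set(np.linspace(1, 2 * inc.T, 40, dtype=int)))
    rows = []
    for t in ts:
        method = "interpolated" if t < inc.T else ("observed" if t == inc.T else "extrapolated")
        rows.append(
            {
                "t": t,
                "qD": hill_shannon(inc, t),
                "coverage": sample_coverage(inc, t),
                "method": method,
            }
        )
    return pd.DataFrame(rows)
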
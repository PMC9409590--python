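"""Rank-based group comparisons for prey length, number, and energy contrasts.

The study workflow for comparing a prey characteristic among diet groups is
non-parametric throughout (the underlying distributions are skewed and often
heteroscedastic):

* variance homogeneous among groups (screened with Levene's test on
  medians) -> Kruskal-Wallis global test, then pairwise Wilcoxon rank-sum
  tests with a Bonferroni adjustment;
* variance heterogeneous -> Welch's heteroscedastic ANOVA computed on the
  global average ranks, then Games-Howell post hoc contrasts (also on
  ranks).

Ties receive average ranks everywhere.  Standard machinery is delegated:
Kruskal-Wallis, rank sums and Levene to scipy, Welch's ANOVA and
Games-Howell to pingouin; this module owns the ranking, the workflow
switch, and the small-sample exact path for the Wilcoxon tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "RankTestResult",
    "kruskal_wallis",
    "pairwise_wilcoxon_bonferroni",
    "welch_anova_on_ranks",
    "games_howell",
    "choose_test",
    "covariate_correlations",
]


@dataclass
class RankTestResult:
    name: str
    statistic: float
    p_value: float
    df: tuple
    extras: dict = field(default_factory=dict)


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(labels))
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    uniq = [u for u in pd.unique(labels)]
    groups = [values[labels == u] for u in uniq]
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    return values, labels, uniq, groups


def kruskal_wallis(values, labels) -> RankTestResult:
    """Kruskal-Wallis rank-sum test with ties correction.

    All values identical is a degenerate but legal input: statistic 0,
    p = 1 (scipy would refuse it).
    """
    values, labels, uniq, groups = _split_groups(values, labels)
    if np.ptp(values) == 0:
        return RankTestResult("Kruskal-Wallis", 0.0, 1.0, (len(uniq) - 1,))
    h, p = stats.kruskal(*groups)
    return RankTestResult("Kruskal-Wallis", float(h), float(p), (len(uniq) - 1,))


def pairwise_wilcoxon_bonferroni(values, labels, exact_below: int = 10) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests, Bonferroni-adjusted.

    Pairs with both sides below ``exact_below`` observations and no ties use
    the exact null distribution; otherwise the normal approximation with
    ties correction.  Adjusted p-values are raw p times the number of pairs,
    capped at 1.
    """
    values, labels, uniq, groups = _split_groups(values, labels)
    pairs = list(combinations(range(len(uniq)), 2))
    rows = []
    for i, j in pairs:
        x, y = groups[i], groups[j]
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        small = min(len(x), len(y)) < exact_below
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {
                "group_a": uniq[i],
                "group_b": uniq[j],
                "U": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_adjusted": min(1.0, float(res.pvalue) * len(pairs)),
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def _rank_frame(values, labels):
    values, labels, uniq, groups = _split_groups(values, labels)
    ranks = stats.rankdata(values)  # global average ranks
    for u in uniq:
        if np.var(ranks[labels == u]) == 0:
            raise ValueError(f"group {u!r} has zero within-group rank variance")
    return pd.DataFrame({"rank": ranks, "group": labels}), uniq


def welch_anova_on_ranks(values, labels) -> RankTestResult:
    """Welch's heteroscedastic ANOVA computed on global average ranks."""
    df, uniq = _rank_frame(values, labels)
    res = pg.welch_anova(data=df, dv="rank", between="group")
    return RankTestResult(
        "Welch-ANOVA-on-ranks",
        float(res["F"].iloc[0]),
        float(res["p_unc"].iloc[0]),
        (float(res["ddof1"].iloc[0]), float(res["ddof2"].iloc[0])),
    )


def games_howell(values, labels) -> pd.DataFrame:
    """Games-Howell post hoc contrasts on global average ranks.

    Returns one row per pair with the t statistic, Welch degrees of freedom,
    and the studentized-range-adjusted p-value.
    """
    df, uniq = _rank_frame(values, labels)
    res = pg.pairwise_gameshowell(data=df, dv="rank", between="group")
    return pd.DataFrame(
        {
            "group_a": res["A"],
            "group_b": res["B"],
            "t": res["T"].astype(float).abs(),
            "df": res["df"].astype(float),
            "p_adjusted": res["pval"].astype(float),
        }
    )


def choose_test(values, labels, alpha: float = 0.05) -> dict:
    """The study's decision rule for comparing a metric among groups.

    Homogeneity of variance is screened with Levene's test centred on
    medians.  Homoscedastic data take the Kruskal-Wallis + pairwise
    Wilcoxon/Bonferroni route; heteroscedastic data take Welch's ANOVA on
    ranks + Games-Howell.  Returns the route, global test and pairwise
    table.
    """
    values, labels, uniq, groups = _split_groups(values, labels)
    lev_stat, lev_p = stats.levene(*groups, center="median")
    if lev_p >= alpha:
        route = "kruskal"
        global_test = kruskal_wallis(values, labels)
        pairwise = pairwise_wilcoxon_bonferroni(values, labels)
    else:
        route = "welch_ranks"
        global_test = welch_anova_on_ranks(values, labels)
        pairwise = games_howell(values, labels)
    return {
        "route": route,
        "levene": RankTestResult("Levene-median", float(lev_stat), float(lev_p), (len(uniq) - 1,)),
        "global": global_test,
        "pairwise": pairwise,
    }


def covariate_correlations(
    stomach_frame: pd.DataFrame,
    covariates: Sequence[str] = ("year", "month", "lat", "lon", "fl_cm"),
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of model covariates."""
    sub = stomach_frame[list(covariates)].astype(float)
    corr = sub.corr(method="pearson", min_periods=min_pairs)
    return corr
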
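"""Per-stomach diet compositions, group summaries, and rare-family lumping.

Proportional prey abundance (p) divides the number of prey per group in an
individual stomach by the total number of prey in that stomach, damping the
influence of prey that are numerous but rare across stomachs.  The analysis
prey groups are families (plus the suborder Hyperiidea and class-level
"Unidentified ..." pools); families contributing no more than the lump
threshold (default 1%) of mean proportional abundance across all stomachs
are lumped into "Other fishes" / "Other cephalopods" / "Other crustaceans".

Group summaries report, per prey group and predator grouping:

* %N  = number of prey_i / total number of prey x 100
* %FO = number of stomachs containing prey_i / total number of stomachs x 100

both with their raw counts, mirroring the layout of a standard diet table.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import Dataset
from .types import BroadGroup, PreyTaxon, StomachRecord

__all__ = [
    "DenominatorWarning",
    "round_half_away",
    "proportional_abundance",
    "build_diet_matrix",
    "mean_proportional_abundance",
    "lump_rare_families",
    "percent_N",
    "percent_FO",
    "diet_summary",
    "summary_from_count_table",
    "check_fo_denominators",
]

OTHER_LABELS = {
    BroadGroup.FISH: "Other fishes",
    BroadGroup.CEPHALOPOD: "Other cephalopods",
    BroadGroup.CRUSTACEAN: "Other crustaceans",
}


class DenominatorWarning(UserWarning):
    """Printed %FO values imply a different stomach count than stated."""


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (matching how diet tables are printed)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def family_group(taxon: PreyTaxon, group_map: Optional[Mapping[str, str]] = None) -> str:
    """The analysis prey-group label of a taxon (family, unless lumped)."""
    if group_map is not None and taxon.family in group_map:
        return group_map[taxon.family]
    return taxon.family


def proportional_abundance(
    stomach: StomachRecord,
    taxa: Mapping[str, PreyTaxon],
    group_map: Optional[Mapping[str, str]] = None,
) -> dict[str, float]:
    """Within-stomach composition over prey groups; values sum to 1."""
    items = stomach.diet_items
    if not items:
        raise ValueError(f"stomach {stomach.stomach_id!r} is empty; caller must filter")
    counts: dict[str, int] = {}
    for p in items:
        g = family_group(taxa[p.taxon_id], group_map)
        counts[g] = counts.get(g, 0) + 1
    total = sum(counts.values())
    return {g: n / total for g, n in counts.items()}


def build_diet_matrix(
    dataset: Dataset, group_map: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Stomachs x prey-groups proportional-abundance matrix.

    Rows are non-empty stomachs (bait removed) and sum to 1; columns are
    ordered prey-group labels.
    """
    rows = {}
    for rec in dataset.non_empty():
        rows[rec.stomach_id] = proportional_abundance(rec, dataset.taxa, group_map)
    dm = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    dm = dm.reindex(index=list(rows), columns=sorted(dm.columns))
    dm.index.name = "stomach_id"
    return dm


def mean_proportional_abundance(
    diet_matrix: pd.DataFrame, subset: Optional[Sequence[str]] = None
) -> pd.Series:
    """Unweighted mean of per-stomach compositions (sums to 1)."""
    dm = diet_matrix if subset is None else diet_matrix.loc[list(subset)]
    if dm.empty:
        raise ValueError("mean proportional abundance over an empty subset")
    return dm.mean(axis=0)


def lump_rare_families(
    pbar: pd.Series,
    family_broad_group: Mapping[str, BroadGroup],
    threshold: float = 0.01,
) -> dict[str, str]:
    """Map each family to its analysis group label.

    ``pbar`` is the mean proportional abundance per family over *all*
    stomachs in the dataset.  Families strictly above the threshold keep
    their own label; the rest are pooled into "Other <broad group>".
    Class-level "Unidentified ..." pools are never lumped: they are not
    families and already aggregate at the broad-group level.
    """
    mapping: dict[str, str] = {}
    for family, p in pbar.items():
        if family.startswith("Unidentified") or p > threshold:
            mapping[family] = family
        else:
            mapping[family] = OTHER_LABELS[BroadGroup(family_broad_group[family])]
    return mapping


def _taxon_label(taxon: PreyTaxon) -> str:
    if taxon.is_unidentified:
        return taxon.family
    if taxon.species:
        return taxon.species
    if taxon.genus:
        return f"{taxon.genus} sp."
    return taxon.family


def diet_summary(
    dataset: Dataset,
    grouping: Mapping[str, str],
    by: str = "taxon",
) -> pd.DataFrame:
    """Per-predator-group diet table with counts, %N, occurrences and %FO.

    ``grouping`` maps every non-empty stomach id to a predator group label
    (e.g. a tree terminal).  ``by`` selects the prey aggregation level:
    ``"taxon"`` (finest identification, as a published diet table prints) or
    ``"family"``.
    """
    rows = []
    for rec in dataset.non_empty():
        g = grouping[rec.stomach_id]
        for p in rec.diet_items:
            t = dataset.taxa[p.taxon_id]
            label = _taxon_label(t) if by == "taxon" else t.family
            rows.append((g, t.family, label, rec.stomach_id))
    long = pd.DataFrame(rows, columns=["group", "family", "prey", "stomach_id"])
    out = []
    for g, sub in long.groupby("group"):
        total_prey = len(sub)
        n_stomachs = sub["stomach_id"].nunique()
        agg = sub.groupby(["family", "prey"]).agg(
            n=("stomach_id", "size"), occurrence=("stomach_id", "nunique")
        )
        for (family, prey), r in agg.iterrows():
            out.append(
                {
                    "group": g,
                    "family": family,
                    "prey": prey,
                    "n": int(r["n"]),
                    "pct_n": 100.0 * r["n"] / total_prey,
                    "occurrence": int(r["occurrence"]),
                    "pct_fo": 100.0 * r["occurrence"] / n_stomachs,
                    "total_prey": total_prey,
                    "n_stomachs": n_stomachs,
                }
            )
    return pd.DataFrame(out)


def percent_N(counts: pd.Series) -> pd.DataFrame:
    """%N per prey group from raw prey counts (one predator grouping).

    ``counts`` is indexed by prey label.  Returns count and percentage;
    percentages are exact (unrounded); round with :func:`round_half_away`
    for table display.
    """
    total = counts.sum()
    if total <= 0:
        raise ValueError("no prey counts")
    return pd.DataFrame({"n": counts, "pct_n": 100.0 * counts / total})


def percent_FO(occurrences: pd.Series, n_stomachs: int) -> pd.DataFrame:
    """%FO per prey group from occurrence counts and the stomach denominator."""
    if n_stomachs <= 0:
        raise ValueError("n_stomachs must be positive")
    if (occurrences > n_stomachs).any():
        raise ValueError("occurrence exceeds the number of stomachs")
    return pd.DataFrame(
        {"occurrence": occurrences, "pct_fo": 100.0 * occurrences / n_stomachs}
    )


def summary_from_count_table(
    counts: pd.DataFrame,
    occurrence: pd.DataFrame,
    n_stomachs: Mapping[str, int],
) -> pd.DataFrame:
    """Recompute %N/%FO from a wide published-style count table.

    ``counts`` and ``occurrence`` are indexed by prey label with one column
    per predator group; ``n_stomachs`` gives the per-group non-empty stomach
    denominators.  Output is long-form with unrounded percentages.
    """
    out = []
    for g in counts.columns:
        pn = percent_N(counts[g][counts[g] > 0])
        fo = percent_FO(occurrence[g][occurrence[g] > 0], n_stomachs[g])
        merged = pn.join(fo, how="outer")
        merged["group"] = g
        merged.index.name = "prey"
        out.append(merged.reset_index())
    return pd.concat(out, ignore_index=True)


def check_fo_denominators(
    occurrence: pd.DataFrame,
    printed_fo: pd.DataFrame,
    n_stomachs: Mapping[str, int],
    search_range: tuple[int, int] = (10, 1000),
) -> dict[str, int]:
    """Infer the stomach denominator implied by printed %FO values.

    For each predator group, scans candidate denominators and keeps the one
    under which the largest number of printed one-decimal %FO values is
    reproduced exactly.  If the best-supported denominator differs from the
    stated stomach count, a :class:`DenominatorWarning` is issued.  Returns
    the implied denominator per group.
    """
    implied: dict[str, int] = {}
    for g in occurrence.columns:
        occ = occurrence[g]
        printed = printed_fo[g]
        mask = (occ > 0) & printed.notna()
        occ, printed = occ[mask].to_numpy(float), printed[mask].to_numpy(float)
        best_n, best_hits = None, -1
        for n in range(search_range[0], search_range[1] + 1):
            hits = sum(
                round_half_away(100.0 * o / n, 1) == p for o, p in zip(occ, printed)
            )
            if hits > best_hits:
                best_n, best_hits = n, hits
        implied[g] = best_n
        if best_n != n_stomachs[g]:
            warnings.warn(
                f"group {g!r}: printed %FO values are consistent with a denominator "
                f"of {best_n} stomachs ({best_hits}/{len(occ)} rows exact), not the "
                f"stated {n_stomachs[g]}",
                DenominatorWarning,
                stacklevel=2,
            )
    return implied
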
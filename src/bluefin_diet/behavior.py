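"""Prey-specific abundance metrics and specialist/generalist classification.

For each predator diet group, and for every prey group found in at least a
threshold fraction of that group's stomachs (default 20%), the *prey-specific
proportion* is the mean proportional abundance of the prey computed only over
stomachs that contain it, and the *prey-specific number* the mean count over
those same stomachs.  Conditioning on presence can only raise the mean, so
the prey-specific proportion always dominates the unconditional mean
proportional abundance.

A mean prey-specific proportion strictly above 0.5 classifies feeding on
that prey as specialist; at or below 0.5 as generalist (a predator filling
half its stomach, on average, with one prey when it takes it at all is the
conventional dividing line of prey-specific abundance diagrams).
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import Dataset
from .composition import family_group

__all__ = ["prey_specific_table", "classify_strategy"]


def classify_strategy(mean_prey_specific_proportion: float, threshold: float = 0.5) -> str:
    """'specialist' iff the mean prey-specific proportion exceeds the threshold."""
    return "specialist" if mean_prey_specific_proportion > threshold else "generalist"


def prey_specific_table(
    dataset: Dataset,
    grouping: Mapping[str, str],
    group_map: Optional[Mapping[str, str]] = None,
    fo_threshold: float = 0.20,
    specialist_threshold: float = 0.5,
) -> pd.DataFrame:
    """Prey-specific proportion/number table per diet group.

    ``grouping`` maps every non-empty stomach to its diet group.  Only prey
    groups with frequency of occurrence >= ``fo_threshold`` within a diet
    group are reported.  Standard deviations are sample (n-1) deviations and
    are missing for single-occurrence prey.
    """
    rows = []
    for rec in dataset.non_empty():
        g = grouping[rec.stomach_id]
        counts: dict[str, int] = {}
        for p in rec.diet_items:
            label = family_group(dataset.taxa[p.taxon_id], group_map)
            counts[label] = counts.get(label, 0) + 1
        total = sum(counts.values())
        for label, n in counts.items():
            rows.append((g, label, rec.stomach_id, n, n / total))
    long = pd.DataFrame(rows, columns=["group", "prey", "stomach_id", "count", "proportion"])

    out = []
    for g, sub in long.groupby("group"):
        n_stomachs = sub["stomach_id"].nunique()
        for prey, psub in sub.groupby("prey"):
            occ = len(psub)
            fo = occ / n_stomachs
            if fo < fo_threshold:
                continue
            mean_p = float(psub["proportion"].mean())
            out.append(
                {
                    "group": g,
                    "prey": prey,
                    "occurrence": occ,
                    "n_stomachs": n_stomachs,
                    "fo": fo,
                    "mean_proportion": mean_p,
                    "sd_proportion": float(psub["proportion"].std(ddof=1)) if occ > 1 else np.nan,
                    "mean_number": float(psub["count"].mean()),
                    "sd_number": float(psub["count"].std(ddof=1)) if occ > 1 else np.nan,
                    "strategy": classify_strategy(mean_p, specialist_threshold),
                }
            )
    return pd.DataFrame(out)
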
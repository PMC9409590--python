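"""Published diet-composition counts for juvenile Pacific bluefin tuna.

The bundled table holds the family/species-level prey counts and stomach
occurrence counts for the three sampling periods of a 2008-2016 stomach
survey in the Southern California Bight (2008; 2009-14; 2015-16), together
with the percentages as they were printed in the published summary table.
It serves two purposes:

* a real-data input from which the %N/%FO summaries can be recomputed and
  validated against their printed values;
* documentation of the period structure the synthetic generator emulates.

``lumped`` flags families that fell below 1% mean proportional abundance
across all stomachs and were pooled into "Other" groups in the published
similarity analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "PERIODS",
    "NONEMPTY_STOMACHS",
    "TOTAL_STOMACHS_SAMPLED",
    "load_reference_counts",
    "reference_wide_tables",
]

PERIODS = ("2008", "2009_14", "2015_16")

#: Non-empty stomachs per sampling period (the %FO denominators as stated).
NONEMPTY_STOMACHS = {"2008": 88, "2009_14": 439, "2015_16": 194}

#: All stomachs processed over the survey, empty ones included.
TOTAL_STOMACHS_SAMPLED = 963


def load_reference_counts() -> pd.DataFrame:
    """The published count table as a DataFrame (one row per prey entry)."""
    with resources.files("bluefin_diet.data").joinpath(
        "scb_bluefin_diet_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def reference_wide_tables():
    """Split the reference table into the wide inputs the summaries expect.

    Returns ``(counts, occurrence, printed_pn, printed_fo)``: each indexed by
    prey label with one column per sampling period.
    """
    df = load_reference_counts().set_index("prey")
    counts = df[[f"n_{p}" for p in PERIODS]].rename(columns=dict(zip([f"n_{p}" for p in PERIODS], PERIODS)))
    occ = df[[f"occ_{p}" for p in PERIODS]].rename(columns=dict(zip([f"occ_{p}" for p in PERIODS], PERIODS)))
    pn = df[[f"printed_pn_{p}" for p in PERIODS]].rename(
        columns=dict(zip([f"printed_pn_{p}" for p in PERIODS], PERIODS))
    )
    fo = df[[f"printed_fo_{p}" for p in PERIODS]].rename(
        columns=dict(zip([f"printed_fo_{p}" for p in PERIODS], PERIODS))
    )
    return counts, occ, pn, fo
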
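"""Prey length reconstruction, hierarchical imputation, mass and energy totals.

Reconstruction proceeds in four stages, mirroring how stomach-content
energetics are built from partially digested material:

1. whole lengths are taken as measured; hard parts (fish vertebrae,
   cephalopod beaks, crustacean carapaces) are converted to whole length via
   the supplied regressions (unidentified squids with measured beaks receive
   the *average* mantle length predicted by all identified-cephalopod
   beak-to-length regressions);
2. unmeasured prey receive the mean length of measured conspecifics,
   hierarchically: same stomach, else same sampling year, else same diet
   group (tree terminal); family-level identifications use family-level
   means along the same hierarchy, and unidentified prey use year-level
   (else group-level) means of their broad group;
3. lengths convert to body mass; cephalopods with measured beaks convert
   beak dimension directly to mass, bypassing length;
4. mass converts to energy via taxon-resolved energy densities, with
   unidentified prey assigned the mean density of identified prey of the
   same broad group in the same year (else diet group).

Stomachs whose reconstructed content mass exceeds 3% of predator body mass
(above the maximum daily ration reported for bluefin tunas of these sizes)
are excluded from mass/energy analyses, as are stomachs with no usable
predator size; both exclusions are logged.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import Dataset, EnergyResolver, RegressionResolver
from .types import (
    AnalysisConfig,
    BroadGroup,
    LengthSource,
    MeasurementKind,
    PreyItem,
    PreyTaxon,
    RegressionKind,
)

logger = logging.getLogger("bluefin_diet")

__all__ = [
    "hardpart_to_length",
    "reconstruct_lengths",
    "impute_lengths",
    "length_to_mass",
    "assign_masses",
    "assign_energies",
    "stomach_totals_and_filter",
    "reconstruct",
]


def hardpart_to_length(
    item: PreyItem,
    taxon: PreyTaxon,
    resolver: RegressionResolver,
    taxa: Optional[Mapping[str, PreyTaxon]] = None,
) -> Optional[float]:
    """Whole length (mm) from a hard-part measurement, or None if unresolvable.

    Unidentified cephalopods with measured beaks are assigned the mean
    prediction over every identified-cephalopod beak-to-length regression in
    the table.
    """
    if item.measurement_kind != MeasurementKind.HARD_PART:
        raise ValueError(f"prey {item.prey_id!r}: not a hard-part measurement")
    if taxon.is_unidentified and taxon.broad_group == BroadGroup.CEPHALOPOD:
        specs = resolver.specs_of_kind(
            RegressionKind.HARDPART_TO_LENGTH, BroadGroup.CEPHALOPOD, taxa
        )
        specs = [s for s in specs if s.scope_level != "broad_group"]
        if not specs:
            return None
        return float(np.mean([s.predict(item.measured_value_mm) for s in specs]))
    spec = resolver.resolve(taxon, RegressionKind.HARDPART_TO_LENGTH)
    if spec is None:
        return None
    return spec.predict(item.measured_value_mm)


def reconstruct_lengths(dataset: Dataset, resolver: RegressionResolver) -> None:
    """Stage 1: set length_mm for measured prey (in place)."""
    n_unresolved = 0
    for rec in dataset.records:
        for item in rec.diet_items:
            taxon = dataset.taxa[item.taxon_id]
            if item.measurement_kind == MeasurementKind.WHOLE_LENGTH:
                item.length_mm = item.measured_value_mm
                item.length_source = LengthSource.MEASURED
            elif item.measurement_kind == MeasurementKind.HARD_PART:
                length = hardpart_to_length(item, taxon, resolver, dataset.taxa)
                if length is None:
                    n_unresolved += 1
                    logger.info(
                        "prey %s (%s): no hard-part regression resolves; left unmeasured",
                        item.prey_id, taxon.display_label,
                    )
                else:
                    item.length_mm = length
                    item.length_source = LengthSource.HARDPART_REGRESSION
    if n_unresolved:
        logger.info("reconstruct_lengths: %d hard-part prey left unmeasured", n_unresolved)


_LEVEL_SOURCES = (
    ("stomach", LengthSource.IMPUTED_STOMACH),
    ("year", LengthSource.IMPUTED_YEAR),
    ("group", LengthSource.IMPUTED_GROUP),
)


def impute_lengths(dataset: Dataset, grouping: Mapping[str, str]) -> None:
    """Stage 2: hierarchical mean-length imputation for unmeasured prey.

    ``grouping`` maps each non-empty stomach to its diet group (tree
    terminal).  Pools are unweighted means of prey whose length came from
    their own remains (measured whole or hard-part regression).  Identified
    prey pool by taxon (family-level IDs by family); unidentified prey pool
    by broad group at year (else group) level only, with
    ``length_source = imputed_fallback``.
    """
    measured: list[tuple[str, str, str, int, str, float]] = []
    year_of = {r.stomach_id: r.year for r in dataset.records}
    for rec in dataset.records:
        for item in rec.diet_items:
            if item.length_source in (LengthSource.MEASURED, LengthSource.HARDPART_REGRESSION):
                t = dataset.taxa[item.taxon_id]
                measured.append(
                    (item.taxon_id, t.family, str(t.broad_group), rec.year,
                     rec.stomach_id, item.length_mm)
                )
    mf = pd.DataFrame(
        measured, columns=["taxon_id", "family", "broad_group", "year", "stomach_id", "length"]
    )

    def pool(keys: list[str], values: tuple) -> Optional[float]:
        if mf.empty:
            return None
        sub = mf
        for k, v in zip(keys, values):
            sub = sub[sub[k] == v]
            if sub.empty:
                return None
        return float(sub["length"].mean())

    n_imputed, n_unresolved = 0, 0
    for rec in dataset.records:
        gid = grouping.get(rec.stomach_id)
        for item in rec.diet_items:
            if item.length_mm is not None:
                continue
            t = dataset.taxa[item.taxon_id]
            if t.is_unidentified:
                value = pool(["broad_group", "year"], (str(t.broad_group), rec.year))
                if value is None and gid is not None and not mf.empty:
                    group_ids = [s for s, g in grouping.items() if g == gid]
                    sub = mf[
                        (mf["broad_group"] == str(t.broad_group))
                        & mf["stomach_id"].isin(group_ids)
                    ]
                    value = None if sub.empty else float(sub["length"].mean())
                if value is not None:
                    item.length_mm = value
                    item.length_source = LengthSource.IMPUTED_FALLBACK
                    n_imputed += 1
                else:
                    n_unresolved += 1
                    logger.info(
                        "prey %s: unidentified with no broad-group pool; length unresolvable",
                        item.prey_id,
                    )
                continue
            key_col = "family" if t.is_family_level else "taxon_id"
            key_val = t.family if t.is_family_level else item.taxon_id
            assigned = False
            for level, source in _LEVEL_SOURCES:
                if level == "stomach":
                    value = pool([key_col, "stomach_id"], (key_val, rec.stomach_id))
                elif level == "year":
                    value = pool([key_col, "year"], (key_val, rec.year))
                else:
                    if gid is None:
                        continue
                    group_ids = [s for s, g in grouping.items() if g == gid]
                    sub = mf[(mf[key_col] == key_val) & mf["stomach_id"].isin(group_ids)]
                    value = None if sub.empty else float(sub["length"].mean())
                if value is not None:
                    item.length_mm = value
                    item.length_source = source
                    n_imputed += 1
                    assigned = True
                    break
            if not assigned:
                n_unresolved += 1
                logger.info(
                    "prey %s (%s): no measured conspecific anywhere; length unresolvable",
                    item.prey_id, t.display_label,
                )
    logger.info("impute_lengths: %d imputed, %d unresolvable", n_imputed, n_unresolved)


def length_to_mass(
    item: PreyItem,
    taxon: PreyTaxon,
    resolver: RegressionResolver,
    taxa: Optional[Mapping[str, PreyTaxon]] = None,
) -> Optional[float]:
    """Body mass (g) for one prey item, or None if no regression resolves.

    Cephalopods with measured beaks take the beak-to-mass route directly
    (mean over all identified-cephalopod beak-to-mass regressions for
    unidentified squids); everything else converts its whole length.
    """
    is_ceph = taxon.broad_group == BroadGroup.CEPHALOPOD
    if is_ceph and item.measurement_kind == MeasurementKind.HARD_PART:
        if taxon.is_unidentified:
            specs = resolver.specs_of_kind(RegressionKind.BEAK_TO_MASS, BroadGroup.CEPHALOPOD, taxa)
            specs = [s for s in specs if s.scope_level != "broad_group"]
            if specs:
                return float(np.mean([s.predict(item.measured_value_mm) for s in specs]))
        else:
            spec = resolver.resolve(taxon, RegressionKind.BEAK_TO_MASS)
            if spec is not None:
                return spec.predict(item.measured_value_mm)
    if item.length_mm is None:
        return None
    if item.length_mm <= 0:
        raise ValueError(f"prey {item.prey_id!r}: non-positive length {item.length_mm}")
    spec = resolver.resolve(taxon, RegressionKind.LENGTH_TO_MASS)
    if spec is None:
        return None
    return spec.predict(item.length_mm)


def assign_masses(dataset: Dataset, resolver: RegressionResolver) -> None:
    """Stage 3: set mass_g (in place); unresolvable prey stay massless."""
    n_unresolved = 0
    for rec in dataset.records:
        for item in rec.diet_items:
            taxon = dataset.taxa[item.taxon_id]
            mass = length_to_mass(item, taxon, resolver, dataset.taxa)
            if mass is None:
                n_unresolved += 1
            else:
                item.mass_g = mass
    if n_unresolved:
        logger.info("assign_masses: %d prey without resolvable mass", n_unresolved)


def assign_energies(
    dataset: Dataset, energy_resolver: EnergyResolver, grouping: Mapping[str, str]
) -> None:
    """Stage 4: set energy_kj (in place).

    Identified prey resolve a density with species -> genus -> family ->
    broad-group fallback.  Unidentified prey use the unweighted mean density
    over identified prey *items* of the same broad group in the same year,
    else in the same diet group; prey with no density anywhere are flagged by
    staying energyless.
    """
    rows = []
    for rec in dataset.records:
        for item in rec.diet_items:
            t = dataset.taxa[item.taxon_id]
            density = None
            if not t.is_unidentified:
                d = energy_resolver.resolve(t)
                density = d.kj_per_g if d is not None else None
            rows.append(
                {
                    "prey": item, "identified": not t.is_unidentified,
                    "broad_group": str(t.broad_group), "year": rec.year,
                    "group": grouping.get(rec.stomach_id), "density": density,
                }
            )
    df = pd.DataFrame(rows)
    ident = df[df["identified"] & df["density"].notna()]
    by_year = ident.groupby(["broad_group", "year"])["density"].mean()
    by_group = ident.groupby(["broad_group", "group"])["density"].mean()
    n_unresolved = 0
    for row in df.itertuples():
        density = row.density
        if pd.isna(density) and not row.identified:
            density = by_year.get((row.broad_group, row.year))
            if pd.isna(density) or density is None:
                density = by_group.get((row.broad_group, row.group))
        if density is None or pd.isna(density):
            n_unresolved += 1
            continue
        if row.prey.mass_g is not None:
            row.prey.energy_kj = row.prey.mass_g * float(density)
    if n_unresolved:
        logger.info("assign_energies: %d prey without resolvable energy density", n_unresolved)


def stomach_totals_and_filter(
    dataset: Dataset, config: Optional[AnalysisConfig] = None
) -> tuple[pd.DataFrame, list[str]]:
    """Per-stomach totals, %BM screening, and the retained stomach set.

    Returns ``(totals, kept_ids)``.  ``totals`` has one row per non-empty
    stomach: prey count, total reconstructed mass and energy, mean individual
    prey energy, content mass as percent of predator body mass (%BM), the
    exclusion flag and its reason.  Exclusion is strict: stomachs above
    ``100 * bm_exclusion`` %BM are dropped from mass/energy analyses, a
    content of exactly 3% is retained.  Stomachs with no predator mass are
    excluded under their own reason code.
    """
    config = config or AnalysisConfig()
    rows = []
    for rec in dataset.non_empty():
        items = rec.diet_items
        masses = [p.mass_g for p in items if p.mass_g is not None]
        energies = [p.energy_kj for p in items if p.energy_kj is not None]
        total_mass = float(np.sum(masses)) if masses else np.nan
        total_energy = float(np.sum(energies)) if energies else np.nan
        pct_bm = np.nan
        reason = ""
        if rec.predator_mass_kg is None:
            reason = "no_predator_mass"
        elif masses:
            pct_bm = 100.0 * total_mass / (rec.predator_mass_kg * 1000.0)
            if pct_bm > 100.0 * config.bm_exclusion:
                reason = "bm_exceeds"
        rows.append(
            {
                "stomach_id": rec.stomach_id,
                "n_prey": len(items),
                "n_mass_resolved": len(masses),
                "total_mass_g": total_mass,
                "total_energy_kj": total_energy,
                "mean_prey_energy_kj": float(np.mean(energies)) if energies else np.nan,
                "pct_body_mass": pct_bm,
                "excluded": bool(reason),
                "exclusion_reason": reason,
            }
        )
    totals = pd.DataFrame(rows)
    kept = totals.loc[~totals["excluded"], "stomach_id"].tolist()
    n_bm = int((totals["exclusion_reason"] == "bm_exceeds").sum())
    n_nomass = int((totals["exclusion_reason"] == "no_predator_mass").sum())
    logger.info(
        "stomach_totals_and_filter: %d retained, %d excluded >%g%% BM, %d without predator mass",
        len(kept), n_bm, 100.0 * config.bm_exclusion, n_nomass,
    )
    return totals, kept


def reconstruct(
    dataset: Dataset,
    resolver: RegressionResolver,
    energy_resolver: EnergyResolver,
    grouping: Mapping[str, str],
    config: Optional[AnalysisConfig] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Run all four stages and return ``(totals, kept_ids)``."""
    reconstruct_lengths(dataset, resolver)
    impute_lengths(dataset, grouping)
    assign_masses(dataset, resolver)
    assign_energies(dataset, energy_resolver, grouping)
    return stomach_totals_and_filter(dataset, config)
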
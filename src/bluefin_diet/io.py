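"""Delimited-text readers/writers, the dataset container, and parameter resolvers.

File dialect is deliberately plain: UTF-8, comma-delimited, header row
required, dot decimal.  Four schemas are read and written:

``stomachs.csv``
    stomach_id, year, month, lat, lon, fl_cm, ol_cm
``prey.csv``
    prey_id, stomach_id, taxon_id, broad_group, family, genus, species,
    measurement_kind, measured_value_mm, is_bait
``regressions.csv``
    scope_level, scope_value, kind, form, a, b, input_unit, output_unit
``energy.csv``
    scope_level, scope_value, kj_per_g

Every exclusion applied on ingest (bait items, empty stomachs) is logged with
counts via the module logger so a run leaves an audit trail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    SCOPE_LEVELS,
    BroadGroup,
    EnergyDensity,
    MeasurementKind,
    PreyItem,
    PreyTaxon,
    RegressionForm,
    RegressionKind,
    RegressionSpec,
    StomachRecord,
)

logger = logging.getLogger("bluefin_diet")

__all__ = [
    "Dataset",
    "SchemaError",
    "IntegrityError",
    "RegressionResolver",
    "EnergyResolver",
    "read_dataset",
    "write_dataset",
    "read_regressions",
    "write_regressions",
    "read_energy_densities",
    "write_energy_densities",
    "derive_predator_size",
]


class SchemaError(ValueError):
    """A required column is missing or a field failed to parse."""


class IntegrityError(ValueError):
    """Cross-table referential or uniqueness violation."""


STOMACH_COLUMNS = ["stomach_id", "year", "month", "lat", "lon", "fl_cm", "ol_cm"]
PREY_COLUMNS = [
    "prey_id",
    "stomach_id",
    "taxon_id",
    "broad_group",
    "family",
    "genus",
    "species",
    "measurement_kind",
    "measured_value_mm",
    "is_bait",
]


@dataclass
class Dataset:
    """Stomach records plus the taxon catalogue they reference."""

    records: list[StomachRecord]
    taxa: dict[str, PreyTaxon]

    def non_empty(self) -> list[StomachRecord]:
        return [r for r in self.records if not r.is_empty]

    def record(self, stomach_id: str) -> StomachRecord:
        for r in self.records:
            if r.stomach_id == stomach_id:
                return r
        raise KeyError(stomach_id)

    def prey_frame(self) -> pd.DataFrame:
        """Flat per-prey-item table (bait included; flagged)."""
        rows = []
        for rec in self.records:
            for p in rec.prey:
                t = self.taxa[p.taxon_id]
                rows.append(
                    {
                        "prey_id": p.prey_id,
                        "stomach_id": rec.stomach_id,
                        "taxon_id": p.taxon_id,
                        "broad_group": str(t.broad_group),
                        "family": t.family,
                        "genus": t.genus,
                        "species": t.species,
                        "measurement_kind": str(p.measurement_kind),
                        "measured_value_mm": p.measured_value_mm,
                        "is_bait": p.is_bait,
                    }
                )
        return pd.DataFrame(
            rows, columns=PREY_COLUMNS
        )

    def stomach_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "stomach_id": rec.stomach_id,
                    "year": rec.year,
                    "month": rec.month,
                    "lat": rec.latitude,
                    "lon": rec.longitude,
                    "fl_cm": rec.fork_length_cm,
                    "ol_cm": rec.operculum_length_cm,
                    "predator_mass_kg": rec.predator_mass_kg,
                    "is_empty": rec.is_empty,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "stomach_id", "year", "month", "lat", "lon", "fl_cm", "ol_cm",
                "predator_mass_kg", "is_empty",
            ],
        )


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value)


def read_dataset(prey_table_path, stomach_table_path) -> Dataset:
    """Read and join the stomach and prey tables.

    Malformed rows are reported with 1-based file line numbers (header is
    line 1).  A prey row referencing an absent stomach raises
    :class:`IntegrityError`; duplicated prey ids likewise.
    """
    stomachs = pd.read_csv(stomach_table_path, dtype={"stomach_id": str}, float_precision="round_trip")
    prey = pd.read_csv(prey_table_path, dtype={"prey_id": str, "stomach_id": str, "taxon_id": str}, float_precision="round_trip")
    _require_columns(stomachs, STOMACH_COLUMNS, stomach_table_path)
    _require_columns(prey, PREY_COLUMNS, prey_table_path)

    dup = prey["prey_id"][prey["prey_id"].duplicated()]
    if not dup.empty:
        raise IntegrityError(f"{prey_table_path}: duplicate prey_id(s) {sorted(dup.unique())}")
    dup_s = stomachs["stomach_id"][stomachs["stomach_id"].duplicated()]
    if not dup_s.empty:
        raise IntegrityError(f"{stomach_table_path}: duplicate stomach_id(s) {sorted(dup_s.unique())}")

    records: dict[str, StomachRecord] = {}
    for idx, row in stomachs.iterrows():
        line = idx + 2
        try:
            year = row["year"]
            if pd.isna(year):
                raise ValueError("year is required")
            month = _opt_float(row["month"])
            records[row["stomach_id"]] = StomachRecord(
                stomach_id=row["stomach_id"],
                year=int(year),
                month=int(month) if month is not None else None,
                latitude=_opt_float(row["lat"]),
                longitude=_opt_float(row["lon"]),
                fork_length_cm=_opt_float(row["fl_cm"]),
                operculum_length_cm=_opt_float(row["ol_cm"]),
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{stomach_table_path}: line {line}: {exc}") from exc

    taxa: dict[str, PreyTaxon] = {}
    n_bait = 0
    for idx, row in prey.iterrows():
        line = idx + 2
        sid = row["stomach_id"]
        if sid not in records:
            raise IntegrityError(
                f"{prey_table_path}: line {line}: prey {row['prey_id']!r} references "
                f"unknown stomach_id {sid!r}"
            )
        try:
            taxon = PreyTaxon(
                taxon_id=row["taxon_id"],
                broad_group=BroadGroup(row["broad_group"]),
                family=str(row["family"]),
                genus=_opt_str(row["genus"]),
                species=_opt_str(row["species"]),
            )
            taxa.setdefault(taxon.taxon_id, taxon)
            item = PreyItem(
                prey_id=row["prey_id"],
                stomach_id=sid,
                taxon_id=row["taxon_id"],
                measurement_kind=MeasurementKind(row["measurement_kind"]),
                measured_value_mm=_opt_float(row["measured_value_mm"]),
                is_bait=bool(row["is_bait"]),
            )
        except ValueError as exc:
            raise SchemaError(f"{prey_table_path}: line {line}: {exc}") from exc
        n_bait += item.is_bait
        records[sid].prey.append(item)

    ds = Dataset(records=list(records.values()), taxa=taxa)
    n_empty = sum(r.is_empty for r in ds.records)
    logger.info(
        "read_dataset: %d stomachs (%d empty after bait removal), %d prey items "
        "(%d bait items flagged and excluded from analyses)",
        len(ds.records), n_empty, len(prey), n_bait,
    )
    return ds


def write_dataset(dataset: Dataset, out_dir) -> tuple[Path, Path]:
    """Write ``stomachs.csv`` and ``prey.csv``; returns the two paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_path, p_path = out / "stomachs.csv", out / "prey.csv"
    dataset.stomach_frame().drop(columns=["predator_mass_kg", "is_empty"]).to_csv(s_path, index=False, float_format="%.17g")
    dataset.prey_frame().to_csv(p_path, index=False, float_format="%.17g")
    return s_path, p_path


# ---------------------------------------------------------------------------
# Parameter resolvers


class _ScopedResolver:
    """Species -> genus -> family -> broad-group fallback over scoped entries."""

    def __init__(self, entries, key=lambda e: (e.scope_level, e.scope_value)):
        self._index = {}
        for e in entries:
            k = key(e)
            if k in self._index:
                raise IntegrityError(f"duplicate entry for scope {k}")
            self._index[k] = e

    def _lookup(self, taxon: PreyTaxon, extra_key=()) -> Optional[object]:
        for level in SCOPE_LEVELS:
            value = taxon.scope_value(level)
            if value is None:
                continue
            hit = self._index.get((level, value) + tuple(extra_key))
            if hit is not None:
                return hit
        return None


class RegressionResolver(_ScopedResolver):
    """Resolve (taxon, kind) -> :class:`RegressionSpec` with taxonomic fallback.

    Exactly one spec resolves for a query, or ``None`` is returned (a miss is
    distinguishable from a match; callers decide whether a miss is an error).
    """

    def __init__(self, specs: Iterable[RegressionSpec]):
        super().__init__(specs, key=lambda s: (s.scope_level, s.scope_value, s.kind))
        self._specs = list(self._index.values())

    def resolve(self, taxon: PreyTaxon, kind: RegressionKind) -> Optional[RegressionSpec]:
        for level in SCOPE_LEVELS + ("predator",):
            value = taxon.scope_value(level) if level != "predator" else taxon.species
            if value is None:
                continue
            hit = self._index.get((level, value, kind))
            if hit is not None:
                return hit
        return None

    def specs_of_kind(
        self, kind: RegressionKind, broad_group: Optional[BroadGroup] = None,
        taxa: Optional[Mapping[str, PreyTaxon]] = None,
    ) -> list[RegressionSpec]:
        """All specs of a kind, optionally restricted to one broad group.

        Restriction by broad group needs the taxon catalogue to map
        species/genus/family scopes back to their broad grouping; specs scoped
        directly at broad-group level match by value.
        """
        out = []
        for s in self._specs:
            if s.kind != kind:
                continue
            if broad_group is None:
                out.append(s)
                continue
            if s.scope_level == "broad_group":
                if s.scope_value == str(broad_group):
                    out.append(s)
            elif taxa is not None:
                for t in taxa.values():
                    if t.broad_group == broad_group and t.scope_value(s.scope_level) == s.scope_value:
                        out.append(s)
                        break
        return out


class EnergyResolver(_ScopedResolver):
    """Resolve a taxon to an energy density with taxonomic fallback."""

    def __init__(self, densities: Iterable[EnergyDensity]):
        super().__init__(densities)

    def resolve(self, taxon: PreyTaxon) -> Optional[EnergyDensity]:
        return self._lookup(taxon)


def read_regressions(path) -> RegressionResolver:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["scope_level", "scope_value", "kind", "form", "a", "b"], path)
    specs = []
    for idx, row in df.iterrows():
        try:
            specs.append(
                RegressionSpec(
                    scope_level=row["scope_level"],
                    scope_value=row["scope_value"],
                    kind=RegressionKind(row["kind"]),
                    form=RegressionForm(row["form"]),
                    coefficients=(float(row["a"]), float(row["b"])),
                    input_unit=row.get("input_unit", "mm") if isinstance(row.get("input_unit"), str) else "mm",
                    output_unit=row.get("output_unit", "mm") if isinstance(row.get("output_unit"), str) else "mm",
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {idx + 2}: {exc}") from exc
    return RegressionResolver(specs)


def write_regressions(specs: Iterable[RegressionSpec], path) -> None:
    rows = [
        {
            "scope_level": s.scope_level,
            "scope_value": s.scope_value,
            "kind": str(s.kind),
            "form": str(s.form),
            "a": s.coefficients[0],
            "b": s.coefficients[1],
            "input_unit": s.input_unit,
            "output_unit": s.output_unit,
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_energy_densities(path) -> EnergyResolver:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["scope_level", "scope_value", "kj_per_g"], path)
    densities = []
    for idx, row in df.iterrows():
        try:
            densities.append(
                EnergyDensity(
                    scope_level=row["scope_level"],
                    scope_value=row["scope_value"],
                    kj_per_g=float(row["kj_per_g"]),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {idx + 2}: {exc}") from exc
    return EnergyResolver(densities)


def write_energy_densities(densities: Iterable[EnergyDensity], path) -> None:
    rows = [
        {"scope_level": d.scope_level, "scope_value": d.scope_value, "kj_per_g": d.kj_per_g}
        for d in densities
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Predator morphometrics

from .types import PREDATOR_TAXON  # noqa: E402  (placed near its single use)


def derive_predator_size(record: StomachRecord, resolver: RegressionResolver) -> StomachRecord:
    """Fill fork length (from operculum length) and predator mass (from FL).

    Fork length measured directly is never overwritten.  A record with
    neither FL nor OL is returned unchanged with ``predator_mass_kg`` left
    ``None``; downstream %BM analyses treat that as "unusable" rather than an
    error, and the omission is logged.
    """
    rec = record
    if rec.fork_length_cm is None and rec.operculum_length_cm is not None:
        spec = resolver.resolve(PREDATOR_TAXON, RegressionKind.OL_TO_FL)
        if spec is None:
            raise IntegrityError("no ol_to_fl regression supplied")
        rec.fork_length_cm = spec.predict(rec.operculum_length_cm)
        rec.fl_estimated_from_ol = True
    if rec.fork_length_cm is not None and rec.predator_mass_kg is None:
        spec = resolver.resolve(PREDATOR_TAXON, RegressionKind.FL_TO_MASS)
        if spec is None:
            raise IntegrityError("no fl_to_mass regression supplied")
        rec.predator_mass_kg = spec.predict(rec.fork_length_cm)
    if rec.fork_length_cm is None:
        logger.info(
            "stomach %s: no fork or operculum length; unusable for %%BM analyses",
            rec.stomach_id,
        )
    return rec
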
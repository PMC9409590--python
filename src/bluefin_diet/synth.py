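"""Synthetic stomach-content datasets with the structure the analyses assume.

The generator emulates a multi-year stomach-sampling program for juvenile
Pacific bluefin tuna in the Southern California Bight: three temporal regimes
with distinct family-level diet compositions (a 2008-like regime dominated by
myctophids and enoploteuthid squids; a diverse 2009-2014-like regime rich in
hyperiid amphipods; a 2015-2016-like regime dominated by pelagic red crab and
northern anchovy), about a quarter of stomachs empty, overdispersed
per-stomach prey totals, taxon-specific lognormal length distributions
(mostly < 10 cm), and partial measurement (some prey measured whole, some
only as hard parts, the rest unmeasured).

Statistical model per regime:

* empty stomachs: Bernoulli(``empty_fraction``);
* per non-empty stomach, a total prey count from a negative binomial with
  mean ``count_mean`` and dispersion (size) ``count_dispersion``, truncated
  at 1;
* a per-stomach composition drawn from a Dirichlet centred on the regime
  composition with total concentration ``dirichlet_concentration`` (small
  values give the high within-regime dissimilarity of a generalist period),
  then taxon counts from a multinomial;
* per-prey lengths lognormal with taxon-specific (log-mean, log-sd);
* measurement kinds drawn independently per prey with probabilities
  ``measured_fraction * (1 - hardpart_fraction)`` (whole length),
  ``measured_fraction * hardpart_fraction`` (hard part), remainder
  unmeasured.  Measured cephalopods always present as beaks (hard parts), as
  in real material.  Hard-part values are generated by *inverting* the
  supplied hard-part-to-length regression, so reconstruction is exactly
  invertible;
* predator fork length uniform in the regime's range; operculum length is
  emitted by inverting the OL->FL regression, and FL itself is withheld for
  a fraction of stomachs to exercise the OL->FL path.

True per-prey lengths, masses and energies are retained in a hidden side
table ("truth") for recovery tests only; they are never visible to the
reconstruction code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    Dataset,
    EnergyResolver,
    RegressionResolver,
    derive_predator_size,
    write_dataset,
    write_energy_densities,
    write_regressions,
)
from .types import (
    PREDATOR_TAXON,
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

__all__ = [
    "RegimeSpec",
    "SyntheticDataset",
    "TAXON_CATALOG",
    "default_regressions",
    "default_energy_densities",
    "default_regimes",
    "generate_dataset",
    "three_regime_fixture",
    "write_synthetic_dataset",
]


def _t(taxon_id, broad_group, family, genus=None, species=None):
    return PreyTaxon(taxon_id, BroadGroup(broad_group), family, genus, species)


#: Prey taxa available to the generator, mirroring the dominant groups of the
#: study system.  "Unidentified" entries stand for class-level identifications.
TAXON_CATALOG: dict[str, PreyTaxon] = {
    t.taxon_id: t
    for t in [
        # cephalopods
        _t("abraliopsis_sp", "cephalopod", "Enoploteuthidae", "Abraliopsis"),
        _t("argonauta_sp", "cephalopod", "Argonautidae", "Argonauta"),
        _t("gonatus_sp", "cephalopod", "Gonatidae", "Gonatus"),
        _t("doryteuthis_opalescens", "cephalopod", "Loliginidae", "Doryteuthis", "Doryteuthis opalescens"),
        _t("octopus_rubescens", "cephalopod", "Octopodidae", "Octopus", "Octopus rubescens"),
        _t("octopoteuthis_sp", "cephalopod", "Octopoteuthidae", "Octopoteuthis"),
        _t("onychoteuthis_borealijaponica", "cephalopod", "Onychoteuthidae", "Onychoteuthis", "Onychoteuthis borealijaponica"),
        _t("dosidicus_gigas", "cephalopod", "Ommastrephidae", "Dosidicus", "Dosidicus gigas"),
        _t("japetella_heathi", "cephalopod", "Amphitretidae", "Japetella", "Japetella heathi"),
        _t("unidentified_cephalopod", "cephalopod", "Unidentified cephalopods"),
        # fishes
        _t("trachurus_symmetricus", "fish", "Carangidae", "Trachurus", "Trachurus symmetricus"),
        _t("sardinops_sagax", "fish", "Clupeidae", "Sardinops", "Sardinops sagax"),
        _t("engraulis_mordax", "fish", "Engraulidae", "Engraulis", "Engraulis mordax"),
        _t("triphoturus_mexicanus", "fish", "Myctophidae", "Triphoturus", "Triphoturus mexicanus"),
        _t("stenobrachius_leucopsaurus", "fish", "Myctophidae", "Stenobrachius", "Stenobrachius leucopsaurus"),
        _t("ceratoscopelus_townsendi", "fish", "Myctophidae", "Ceratoscopelus", "Ceratoscopelus townsendi"),
        _t("diaphus_theta", "fish", "Myctophidae", "Diaphus", "Diaphus theta"),
        _t("myctophidae_family", "fish", "Myctophidae"),
        _t("cololabis_saira", "fish", "Scomberesocidae", "Cololabis", "Cololabis saira"),
        _t("scomber_japonicus", "fish", "Scombridae", "Scomber", "Scomber japonicus"),
        _t("sebastes_sp", "fish", "Sebastidae", "Sebastes"),
        _t("merluccius_productus", "fish", "Merlucciidae", "Merluccius", "Merluccius productus"),
        _t("chilara_taylori", "fish", "Ophidiidae", "Chilara", "Chilara taylori"),
        _t("unidentified_fish", "fish", "Unidentified fishes"),
        # crustaceans
        _t("hyperiidea", "crustacean", "Hyperiidea"),
        _t("phronima_sp", "crustacean", "Hyperiidea", "Phronima"),
        _t("pleuroncodes_planipes", "crustacean", "Munididae", "Pleuroncodes", "Pleuroncodes planipes"),
        _t("unidentified_malacostraca", "crustacean", "Unidentified crustaceans"),
    ]
}

#: Taxon-level lognormal length parameters (log-mean of mm, log-sd).  Typical
#: sizes: myctophids 3-5 cm SL, enoploteuthid squids ~3 cm ML, hyperiids
#: ~1.5 cm TL, pelagic red crab ~2.6 cm TL, anchovy ~8 cm SL.
DEFAULT_LENGTH_PARAMS: dict[str, tuple[float, float]] = {
    "abraliopsis_sp": (np.log(30.0), 0.25),
    "argonauta_sp": (np.log(25.0), 0.25),
    "gonatus_sp": (np.log(35.0), 0.30),
    "doryteuthis_opalescens": (np.log(60.0), 0.30),
    "octopus_rubescens": (np.log(30.0), 0.30),
    "octopoteuthis_sp": (np.log(35.0), 0.30),
    "onychoteuthis_borealijaponica": (np.log(55.0), 0.30),
    "dosidicus_gigas": (np.log(90.0), 0.30),
    "japetella_heathi": (np.log(30.0), 0.25),
    "unidentified_cephalopod": (np.log(35.0), 0.35),
    "trachurus_symmetricus": (np.log(70.0), 0.30),
    "sardinops_sagax": (np.log(95.0), 0.20),
    "engraulis_mordax": (np.log(80.0), 0.20),
    "triphoturus_mexicanus": (np.log(40.0), 0.20),
    "stenobrachius_leucopsaurus": (np.log(45.0), 0.20),
    "ceratoscopelus_townsendi": (np.log(45.0), 0.20),
    "diaphus_theta": (np.log(40.0), 0.20),
    "myctophidae_family": (np.log(42.0), 0.25),
    "cololabis_saira": (np.log(120.0), 0.25),
    "scomber_japonicus": (np.log(110.0), 0.25),
    "sebastes_sp": (np.log(35.0), 0.30),
    "merluccius_productus": (np.log(80.0), 0.30),
    "chilara_taylori": (np.log(70.0), 0.30),
    "unidentified_fish": (np.log(50.0), 0.35),
    "hyperiidea": (np.log(15.0), 0.25),
    "phronima_sp": (np.log(20.0), 0.25),
    "pleuroncodes_planipes": (np.log(26.0), 0.20),
    "unidentified_malacostraca": (np.log(18.0), 0.35),
}


def default_regressions() -> list[RegressionSpec]:
    """Synthetic allometric parameter table.

    Coefficient values are plausible for small pelagic prey but are synthetic
    stand-ins, not published estimates; real analyses must supply their own
    table.  For cephalopod families the beak->mass power law is constructed
    as the exact composition of beak->length and length->mass so that the two
    reconstruction routes agree.
    """
    specs: list[RegressionSpec] = []

    def add(level, value, kind, form, a, b, iu="mm", ou="mm"):
        specs.append(RegressionSpec(level, value, RegressionKind(kind), RegressionForm(form), (a, b), iu, ou))

    # hard part -> whole length (fish vertebrae, crustacean carapaces): linear
    add("broad_group", "fish", "hardpart_to_length", "linear", 0.0, 12.0)
    add("broad_group", "crustacean", "hardpart_to_length", "linear", 0.0, 2.6)
    # cephalopod beaks: rostral length -> mantle length, power laws per family
    ceph_beak_length = {
        "Enoploteuthidae": (18.0, 0.95),
        "Argonautidae": (16.0, 0.95),
        "Gonatidae": (20.0, 0.95),
        "Loliginidae": (24.0, 1.00),
        "Octopodidae": (15.0, 0.95),
        "Octopoteuthidae": (20.0, 0.95),
        "Onychoteuthidae": (22.0, 1.00),
        "Ommastrephidae": (26.0, 1.00),
        "Amphitretidae": (16.0, 0.95),
    }
    ceph_length_mass = (4.0e-4, 2.2)  # ML mm -> g
    for fam, (a, b) in ceph_beak_length.items():
        add("family", fam, "hardpart_to_length", "power", a, b)
        # beak -> mass = (length -> mass) o (beak -> length), exact composition
        am, bm = ceph_length_mass
        add("family", fam, "beak_to_mass", "power", am * a**bm, b * bm, "mm", "g")
    add("broad_group", "cephalopod", "length_to_mass", "power", *ceph_length_mass, "mm", "g")
    # length -> mass (SL mm -> g), power laws
    add("broad_group", "fish", "length_to_mass", "power", 1.0e-5, 3.0, "mm", "g")
    add("family", "Engraulidae", "length_to_mass", "power", 6.0e-6, 3.1, "mm", "g")
    add("family", "Clupeidae", "length_to_mass", "power", 8.0e-6, 3.05, "mm", "g")
    add("family", "Myctophidae", "length_to_mass", "power", 1.5e-5, 2.95, "mm", "g")
    add("broad_group", "crustacean", "length_to_mass", "power", 4.0e-5, 2.8, "mm", "g")
    add("family", "Munididae", "length_to_mass", "power", 6.0e-5, 2.75, "mm", "g")
    # predator morphometrics: OL -> FL linear (cm), FL -> mass power (cm -> kg)
    add("predator", "Thunnus orientalis", "ol_to_fl", "linear", 0.0, 4.0, "cm", "cm")
    add("predator", "Thunnus orientalis", "fl_to_mass", "power", 2.0e-5, 3.0, "cm", "kg")
    return specs


def default_energy_densities() -> list[EnergyDensity]:
    """Synthetic wet-mass energy densities (kJ/g), typical for each group.

    Identified taxa resolve at species or family level; "Unidentified"
    catch-alls deliberately have no entry so the year/group-average fallback
    path is exercised.
    """
    rows = [
        ("family", "Engraulidae", 6.5),
        ("family", "Clupeidae", 7.0),
        ("family", "Myctophidae", 8.0),
        ("family", "Carangidae", 5.5),
        ("family", "Scombridae", 6.0),
        ("family", "Scomberesocidae", 6.0),
        ("family", "Sebastidae", 4.5),
        ("family", "Merlucciidae", 4.5),
        ("family", "Ophidiidae", 4.5),
        ("broad_group", "fish", 5.5),
        ("family", "Enoploteuthidae", 5.0),
        ("family", "Gonatidae", 4.5),
        ("broad_group", "cephalopod", 4.0),
        ("family", "Hyperiidea", 3.0),
        ("family", "Munididae", 3.5),
        ("broad_group", "crustacean", 3.2),
    ]
    return [EnergyDensity(level, value, kj) for level, value, kj in rows]


@dataclass
class RegimeSpec:
    """Parameters for one temporal sampling regime."""

    label: str
    n_stomachs: int
    composition: dict[str, float]
    count_mean: float = 25.0
    count_dispersion: float = 1.0
    empty_fraction: float = 0.25
    dirichlet_concentration: float = 5.0
    length_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    measured_fraction: float = 0.45
    hardpart_fraction: float = 0.67
    predator_fl_range: tuple[float, float] = (60.0, 150.0)
    years: tuple[int, ...] = (2008,)
    month_range: tuple[int, int] = (6, 9)
    fl_missing_fraction: float = 0.15
    size_missing_fraction: float = 0.02
    bait_fraction: float = 0.02

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"regime {self.label!r}: composition sums to {total}, not 1")
        for name in ("empty_fraction", "measured_fraction", "hardpart_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"regime {self.label!r}: {name}={v} outside [0, 1]")
        unknown = set(self.composition) - set(TAXON_CATALOG)
        if unknown:
            raise ValueError(f"regime {self.label!r}: unknown taxa {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its hidden ground truth."""

    dataset: Dataset
    regressions: list[RegressionSpec]
    energy_densities: list[EnergyDensity]
    truth: pd.DataFrame  # prey_id, stomach_id, taxon_id, regime, true_length_mm, true_mass_g, true_energy_kj
    regime_of: dict[str, str]  # stomach_id -> regime label


def _normalised(composition: dict[str, float]) -> dict[str, float]:
    total = sum(composition.values())
    return {k: v / total for k, v in composition.items()}


def default_regimes(
    n_stomachs: tuple[int, int, int] = (40, 160, 100), **overrides
) -> list[RegimeSpec]:
    """The three study-like regimes (sizes default to a ~300-stomach fixture).

    Keyword overrides are applied to every regime (e.g.
    ``measured_fraction=1.0`` for exact-recovery experiments).
    """
    early = _normalised({
        # myctophid + enoploteuthid dominated, tight within-regime similarity
        "triphoturus_mexicanus": 0.190,
        "stenobrachius_leucopsaurus": 0.080,
        "ceratoscopelus_townsendi": 0.050,
        "diaphus_theta": 0.040,
        "abraliopsis_sp": 0.290,
        "unidentified_malacostraca": 0.120,
        "onychoteuthis_borealijaponica": 0.025,
        "gonatus_sp": 0.015,
        "dosidicus_gigas": 0.010,
        "unidentified_cephalopod": 0.030,
        "unidentified_fish": 0.030,
        "doryteuthis_opalescens": 0.010,
        "sebastes_sp": 0.010,
        "sardinops_sagax": 0.005,
        "engraulis_mordax": 0.005,
        "cololabis_saira": 0.005,
        "myctophidae_family": 0.005,
        "argonauta_sp": 0.005,
        "phronima_sp": 0.005,
        "octopoteuthis_sp": 0.005,
        "trachurus_symmetricus": 0.005,
        "scomber_japonicus": 0.005,
        "merluccius_productus": 0.005,
        "chilara_taylori": 0.005,
        "japetella_heathi": 0.005,
        "octopus_rubescens": 0.005,
        "hyperiidea": 0.020,
        "pleuroncodes_planipes": 0.025,
    })
    middle = _normalised({
        # diverse diet; hyperiid amphipods ~0.22 at family level
        "hyperiidea": 0.190,
        "phronima_sp": 0.030,
        "unidentified_cephalopod": 0.130,
        "trachurus_symmetricus": 0.100,
        "gonatus_sp": 0.060,
        "octopoteuthis_sp": 0.050,
        "sebastes_sp": 0.050,
        "unidentified_malacostraca": 0.050,
        "onychoteuthis_borealijaponica": 0.045,
        "doryteuthis_opalescens": 0.040,
        "octopus_rubescens": 0.040,
        "scomber_japonicus": 0.040,
        "engraulis_mordax": 0.030,
        "argonauta_sp": 0.025,
        "cololabis_saira": 0.025,
        "unidentified_fish": 0.025,
        "sardinops_sagax": 0.020,
        "merluccius_productus": 0.010,
        "chilara_taylori": 0.010,
        "dosidicus_gigas": 0.005,
        "japetella_heathi": 0.005,
        "abraliopsis_sp": 0.005,
        "diaphus_theta": 0.005,
        "triphoturus_mexicanus": 0.005,
        "pleuroncodes_planipes": 0.005,
    })
    late = _normalised({
        # pelagic red crab + anchovy dominated
        "pleuroncodes_planipes": 0.520,
        "engraulis_mordax": 0.140,
        "sebastes_sp": 0.050,
        "unidentified_malacostraca": 0.045,
        "unidentified_fish": 0.040,
        "unidentified_cephalopod": 0.035,
        "sardinops_sagax": 0.030,
        "hyperiidea": 0.030,
        "doryteuthis_opalescens": 0.020,
        "onychoteuthis_borealijaponica": 0.020,
        "phronima_sp": 0.015,
        "trachurus_symmetricus": 0.015,
        "gonatus_sp": 0.010,
        "chilara_taylori": 0.010,
        "argonauta_sp": 0.005,
        "ceratoscopelus_townsendi": 0.005,
        "cololabis_saira": 0.005,
        "scomber_japonicus": 0.005,
    })
    regimes = [
        RegimeSpec(
            label="2008",
            n_stomachs=n_stomachs[0],
            composition=early,
            count_mean=22.7,
            count_dispersion=1.2,
            dirichlet_concentration=10.0,
            predator_fl_range=(61.0, 93.0),
            years=(2008,),
            month_range=(6, 9),
        ),
        RegimeSpec(
            label="2009-14",
            n_stomachs=n_stomachs[1],
            composition=middle,
            count_mean=34.4,
            count_dispersion=1.0,
            dirichlet_concentration=2.5,
            predator_fl_range=(42.0, 174.0),
            years=tuple(range(2009, 2015)),
            month_range=(1, 10),
        ),
        RegimeSpec(
            label="2015-16",
            n_stomachs=n_stomachs[2],
            composition=late,
            count_mean=20.1,
            count_dispersion=0.6,
            dirichlet_concentration=5.0,
            predator_fl_range=(60.0, 150.0),
            years=(2015, 2016),
            month_range=(5, 9),
        ),
    ]
    if overrides:
        regimes = [replace(r, **overrides) for r in regimes]
    return regimes


def generate_dataset(
    regimes: Sequence[RegimeSpec],
    regressions: Optional[Iterable[RegressionSpec]] = None,
    energy_densities: Optional[Iterable[EnergyDensity]] = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw a full synthetic dataset under the given regime specifications.

    Deterministic under a fixed seed.  Hidden truth masses use the same
    conversion route the reconstruction stage would take with complete
    information: beak->mass for cephalopods, length->mass otherwise; truth
    energies for class-level "Unidentified" prey follow the year-average
    density assignment rule (there is no other defensible ground truth for a
    prey with no identity).
    """
    if not regimes:
        raise ValueError("at least one regime is required")
    rng = np.random.default_rng(seed)
    specs = list(regressions) if regressions is not None else default_regressions()
    densities = (
        list(energy_densities) if energy_densities is not None else default_energy_densities()
    )
    resolver = RegressionResolver(specs)
    energy_resolver = EnergyResolver(densities)

    records: list[StomachRecord] = []
    truth_rows: list[dict] = []
    regime_of: dict[str, str] = {}

    for ri, regime in enumerate(regimes, start=1):
        taxa_ids = sorted(regime.composition)
        base = np.array([regime.composition[t] for t in taxa_ids])
        length_params = {**DEFAULT_LENGTH_PARAMS, **regime.length_params}
        for si in range(regime.n_stomachs):
            sid = f"R{ri}-S{si + 1:04d}"
            regime_of[sid] = regime.label
            year = int(rng.choice(regime.years))
            month = int(rng.integers(regime.month_range[0], regime.month_range[1] + 1))
            lat = float(rng.uniform(32.0, 33.5))
            lon = float(rng.uniform(-119.5, -117.0))
            fl = float(rng.uniform(*regime.predator_fl_range))
            u_size = rng.random()
            ol_spec = resolver.resolve(PREDATOR_TAXON, RegressionKind.OL_TO_FL)
            ol = ol_spec.invert(fl) if ol_spec is not None else None
            rec = StomachRecord(
                stomach_id=sid, year=year, month=month, latitude=lat, longitude=lon,
                fork_length_cm=fl, operculum_length_cm=ol,
            )
            if u_size < regime.size_missing_fraction:
                rec.fork_length_cm = None
                rec.operculum_length_cm = None
            elif u_size < regime.size_missing_fraction + regime.fl_missing_fraction:
                rec.fork_length_cm = None  # head-only donation: OL survives

            is_empty = rng.random() < regime.empty_fraction
            if not is_empty:
                k = regime.count_dispersion
                p = k / (k + regime.count_mean)
                total = max(1, int(rng.negative_binomial(k, p)))
                alpha = regime.dirichlet_concentration * base
                probs = rng.dirichlet(np.maximum(alpha, 1e-6))
                counts = rng.multinomial(total, probs)
                pi = 0
                for taxon_id, n in zip(taxa_ids, counts):
                    taxon = TAXON_CATALOG[taxon_id]
                    mu, sd = length_params[taxon_id]
                    for _ in range(int(n)):
                        pi += 1
                        pid = f"{sid}-P{pi:04d}"
                        true_len = float(np.exp(rng.normal(mu, sd)))
                        item, true_mass = _materialise_prey(
                            pid, sid, taxon, true_len, regime, rng, resolver
                        )
                        rec.prey.append(item)
                        truth_rows.append(
                            {
                                "prey_id": pid,
                                "stomach_id": sid,
                                "taxon_id": taxon_id,
                                "regime": regime.label,
                                "true_length_mm": true_len,
                                "true_mass_g": true_mass,
                                "true_energy_kj": np.nan,  # filled below
                            }
                        )
                # occasional bait item, excluded from all analyses
                if rng.random() < regime.bait_fraction:
                    bait_taxon = TAXON_CATALOG[
                        "sardinops_sagax" if rng.random() < 0.5 else "engraulis_mordax"
                    ]
                    rec.prey.append(
                        PreyItem(
                            prey_id=f"{sid}-BAIT",
                            stomach_id=sid,
                            taxon_id=bait_taxon.taxon_id,
                            measurement_kind=MeasurementKind.WHOLE_LENGTH,
                            measured_value_mm=float(rng.uniform(115.0, 160.0)),
                            is_bait=True,
                        )
                    )
            records.append(derive_predator_size(rec, resolver))

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "prey_id", "stomach_id", "taxon_id", "regime",
            "true_length_mm", "true_mass_g", "true_energy_kj",
        ],
    )
    dataset = Dataset(records=records, taxa=dict(TAXON_CATALOG))
    if not truth.empty:
        truth["true_energy_kj"] = _truth_energy(truth, dataset, energy_resolver, regime_of)
    return SyntheticDataset(
        dataset=dataset,
        regressions=specs,
        energy_densities=densities,
        truth=truth,
        regime_of=regime_of,
    )


def _materialise_prey(pid, sid, taxon, true_len, regime, rng, resolver):
    """Assign a measurement presentation to one prey and return its truth mass."""
    hp_spec = resolver.resolve(taxon, RegressionKind.HARDPART_TO_LENGTH)
    u = rng.random()
    p_whole = regime.measured_fraction * (1.0 - regime.hardpart_fraction)
    p_hard = regime.measured_fraction * regime.hardpart_fraction
    is_ceph = taxon.broad_group == BroadGroup.CEPHALOPOD
    if u < p_whole + p_hard and is_ceph and hp_spec is not None:
        kind = MeasurementKind.HARD_PART  # measured cephalopods present as beaks
    elif u < p_whole:
        kind = MeasurementKind.WHOLE_LENGTH
    elif u < p_whole + p_hard and hp_spec is not None:
        kind = MeasurementKind.HARD_PART
    elif u < p_whole + p_hard:
        kind = MeasurementKind.WHOLE_LENGTH  # no hard-part regression: fall back
    else:
        kind = MeasurementKind.UNMEASURED

    measured = None
    if kind == MeasurementKind.WHOLE_LENGTH:
        measured = true_len
    elif kind == MeasurementKind.HARD_PART:
        measured = hp_spec.invert(true_len)

    # truth mass by the same route full information would take
    beak_spec = resolver.resolve(taxon, RegressionKind.BEAK_TO_MASS)
    if is_ceph and kind == MeasurementKind.HARD_PART and beak_spec is not None:
        true_mass = beak_spec.predict(measured)
    else:
        lm_spec = resolver.resolve(taxon, RegressionKind.LENGTH_TO_MASS)
        true_mass = lm_spec.predict(true_len) if lm_spec is not None else np.nan
    item = PreyItem(
        prey_id=pid, stomach_id=sid, taxon_id=taxon.taxon_id,
        measurement_kind=kind, measured_value_mm=measured,
    )
    return item, true_mass


def _truth_energy(truth, dataset, energy_resolver, regime_of):
    """Truth energies; unidentified prey use the year-average identified density."""
    year_of = {r.stomach_id: r.year for r in dataset.records}
    taxa = dataset.taxa
    densities = np.full(len(truth), np.nan)
    identified = np.array([not taxa[t].is_unidentified for t in truth["taxon_id"]])
    for i, taxon_id in enumerate(truth["taxon_id"]):
        if identified[i]:
            d = energy_resolver.resolve(taxa[taxon_id])
            densities[i] = d.kj_per_g if d is not None else np.nan
    tmp = truth.assign(
        density=densities,
        year=[year_of[s] for s in truth["stomach_id"]],
        broad_group=[str(taxa[t].broad_group) for t in truth["taxon_id"]],
    )
    # per (broad_group, year) mean density over identified prey items
    grp = tmp[identified].groupby(["broad_group", "year"])["density"].mean()
    glob = tmp[identified].groupby("broad_group")["density"].mean()
    for i in np.flatnonzero(~identified):
        key = (tmp.at[i, "broad_group"], tmp.at[i, "year"])
        densities[i] = grp.get(key, glob.get(tmp.at[i, "broad_group"], np.nan))
    return truth["true_mass_g"].to_numpy() * densities


def three_regime_fixture(seed: int = 0, n_stomachs=(40, 160, 100), **overrides) -> SyntheticDataset:
    """A ~300-stomach dataset with the three study-like regimes.

    The year covariate encodes the regime, so a correctly working
    compositional tree should recover exactly three year-split groups.
    ``overrides`` are forwarded to every :class:`RegimeSpec` (e.g.
    ``measured_fraction=1.0``).
    """
    return generate_dataset(default_regimes(n_stomachs, **overrides), seed=seed)


def write_synthetic_dataset(synth: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the core CSV schemas plus the hidden-truth side table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s_path, p_path = write_dataset(synth.dataset, out)
    r_path = out / "regressions.csv"
    e_path = out / "energy.csv"
    t_path = out / "truth.csv"
    write_regressions(synth.regressions, r_path)
    write_energy_densities(synth.energy_densities, e_path)
    synth.truth.to_csv(t_path, index=False, float_format="%.17g")
    return {
        "stomachs": s_path, "prey": p_path, "regressions": r_path,
        "energy": e_path, "truth": t_path,
    }
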
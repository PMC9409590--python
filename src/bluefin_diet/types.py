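"""Core domain types shared by every stage of the diet-analysis pipeline.

The unit of observation is a single predator stomach (:class:`StomachRecord`)
holding individual prey items (:class:`PreyItem`).  Prey are identified to the
lowest possible taxonomic level and carried through the pipeline as
:class:`PreyTaxon` entries; prey not identified at least to family are pooled
per broad taxonomic grouping (fishes, cephalopods, crustaceans).  Hyperiid
amphipods are grouped at the suborder level ("Hyperiidea") and treated as a
family-rank label throughout.

Allometric conversions (hard part -> whole length, length -> mass, beak ->
mass, operculum length -> fork length, fork length -> mass) are user-supplied
parameter tables (:class:`RegressionSpec`); energetic conversions are supplied
as wet-mass energy densities (:class:`EnergyDensity`).  Nothing allometric is
hard-coded.

Internal units: prey lengths in mm (standard length for fishes, mantle length
for cephalopods, total length for crustaceans), prey mass in g, energy in kJ;
predator fork/operculum length in cm and predator mass in kg.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import yaml

__all__ = [
    "BroadGroup",
    "MeasurementKind",
    "LengthSource",
    "RegressionKind",
    "RegressionForm",
    "PreyTaxon",
    "PreyItem",
    "StomachRecord",
    "RegressionSpec",
    "EnergyDensity",
    "AnalysisConfig",
    "PREDATOR_TAXON",
]


class BroadGroup(enum.StrEnum):
    FISH = "fish"
    CEPHALOPOD = "cephalopod"
    CRUSTACEAN = "crustacean"


class MeasurementKind(enum.StrEnum):
    WHOLE_LENGTH = "whole_length"
    HARD_PART = "hard_part"
    UNMEASURED = "unmeasured"


class LengthSource(enum.StrEnum):
    MEASURED = "measured"
    HARDPART_REGRESSION = "hardpart_regression"
    IMPUTED_STOMACH = "imputed_stomach"
    IMPUTED_YEAR = "imputed_year"
    IMPUTED_GROUP = "imputed_group"
    IMPUTED_FALLBACK = "imputed_fallback"


class RegressionKind(enum.StrEnum):
    HARDPART_TO_LENGTH = "hardpart_to_length"
    LENGTH_TO_MASS = "length_to_mass"
    BEAK_TO_MASS = "beak_to_mass"
    OL_TO_FL = "ol_to_fl"
    FL_TO_MASS = "fl_to_mass"


class RegressionForm(enum.StrEnum):
    LINEAR = "linear"          # y = a + b*x
    POWER = "power"            # y = a * x**b
    LOG_LINEAR = "log_linear"  # log10(y) = a + b*log10(x)


#: Taxonomic levels tried, most to least specific, when resolving a
#: regression or energy density for a prey taxon.
SCOPE_LEVELS = ("species", "genus", "family", "broad_group")


@dataclass(frozen=True)
class PreyTaxon:
    """A prey taxon at the finest identified rank.

    ``family`` is always populated: either a true family name, the suborder
    label "Hyperiidea", or "Unidentified <fishes|cephalopods|crustaceans>"
    for class-level identifications.
    """

    taxon_id: str
    broad_group: BroadGroup
    family: str
    genus: Optional[str] = None
    species: Optional[str] = None
    display_label: str = ""

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError(f"taxon {self.taxon_id!r}: family must be non-empty")
        if not self.display_label:
            object.__setattr__(
                self, "display_label", self.species or self.genus or self.family
            )

    @property
    def is_unidentified(self) -> bool:
        """True for class-level IDs pooled per broad grouping."""
        return self.family.startswith("Unidentified")

    @property
    def is_family_level(self) -> bool:
        """Identified to family (or suborder) but no further."""
        return not self.is_unidentified and self.genus is None and self.species is None

    def scope_value(self, level: str) -> Optional[str]:
        if level == "broad_group":
            return str(self.broad_group)
        return getattr(self, level)


@dataclass
class PreyItem:
    """One prey individual recovered from a stomach.

    ``measured_value_mm`` is the raw measurement: a whole-body length when
    ``measurement_kind`` is ``whole_length``, a hard-part dimension (vertebra,
    beak rostral length, carapace) when ``hard_part``.  ``length_mm``,
    ``mass_g`` and ``energy_kj`` are filled in by the reconstruction stage and
    ``length_source`` records provenance.  Bait items are flagged on ingest
    and excluded from every analysis.
    """

    prey_id: str
    stomach_id: str
    taxon_id: str
    measurement_kind: MeasurementKind = MeasurementKind.UNMEASURED
    measured_value_mm: Optional[float] = None
    length_mm: Optional[float] = None
    length_source: Optional[LengthSource] = None
    mass_g: Optional[float] = None
    energy_kj: Optional[float] = None
    is_bait: bool = False

    def __post_init__(self) -> None:
        has_value = self.measured_value_mm is not None
        if has_value != (self.measurement_kind != MeasurementKind.UNMEASURED):
            raise ValueError(
                f"prey {self.prey_id!r}: measured_value_mm must be present iff "
                f"measurement_kind is not 'unmeasured'"
            )
        if has_value and not self.measured_value_mm > 0:
            raise ValueError(f"prey {self.prey_id!r}: measured_value_mm must be > 0")


@dataclass
class StomachRecord:
    """One sampled predator with covariates and its prey items."""

    stomach_id: str
    year: int
    month: Optional[int] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    fork_length_cm: Optional[float] = None
    operculum_length_cm: Optional[float] = None
    predator_mass_kg: Optional[float] = None
    prey: list[PreyItem] = field(default_factory=list)
    fl_estimated_from_ol: bool = False

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"stomach {self.stomach_id!r}: month {self.month} out of range")

    @property
    def diet_items(self) -> list[PreyItem]:
        """Prey items entering analyses (bait removed)."""
        return [p for p in self.prey if not p.is_bait]

    @property
    def is_empty(self) -> bool:
        return len(self.diet_items) == 0


@dataclass(frozen=True)
class RegressionSpec:
    """One allometric conversion, scoped to a taxonomic level.

    ``coefficients`` are ordered ``(a, b)`` for every supported form (see
    :class:`RegressionForm`).  Units are declared, not assumed; readers
    validate them against the pipeline's internal conventions.
    """

    scope_level: str
    scope_value: str
    kind: RegressionKind
    form: RegressionForm
    coefficients: tuple[float, ...]
    input_unit: str = "mm"
    output_unit: str = "mm"

    def __post_init__(self) -> None:
        if self.scope_level not in SCOPE_LEVELS and self.scope_level != "predator":
            raise ValueError(f"unknown scope level {self.scope_level!r}")
        if len(self.coefficients) != 2:
            raise ValueError(f"{self.kind}: expected 2 coefficients, got {len(self.coefficients)}")
        if not all(math.isfinite(c) for c in self.coefficients):
            raise ValueError(f"{self.kind} for {self.scope_value!r}: non-finite coefficient")

    def predict(self, x: float) -> float:
        """Evaluate the regression at ``x`` (units as declared)."""
        if x <= 0:
            raise ValueError(f"regression input must be positive, got {x}")
        a, b = self.coefficients
        if self.form is RegressionForm.LINEAR:
            return a + b * x
        if self.form is RegressionForm.POWER:
            return a * x**b
        return 10.0 ** (a + b * math.log10(x))

    def invert(self, y: float) -> float:
        """Solve ``predict(x) = y`` for ``x`` (used to emit synthetic hard parts)."""
        a, b = self.coefficients
        if b == 0:
            raise ValueError("cannot invert a constant regression")
        if self.form is RegressionForm.LINEAR:
            return (y - a) / b
        if self.form is RegressionForm.POWER:
            return (y / a) ** (1.0 / b)
        return 10.0 ** ((math.log10(y) - a) / b)


@dataclass(frozen=True)
class EnergyDensity:
    """Wet-mass energy density (kJ per g) scoped to a taxonomic level."""

    scope_level: str
    scope_value: str
    kj_per_g: float

    def __post_init__(self) -> None:
        if self.scope_level not in SCOPE_LEVELS:
            raise ValueError(f"unknown scope level {self.scope_level!r}")
        if not self.kj_per_g > 0:
            raise ValueError(f"energy density for {self.scope_value!r} must be > 0")


#: The predator itself, used to resolve OL->FL and FL->mass conversions.
PREDATOR_TAXON = PreyTaxon(
    taxon_id="thunnus_orientalis",
    broad_group=BroadGroup.FISH,
    family="Scombridae",
    genus="Thunnus",
    species="Thunnus orientalis",
    display_label="Pacific bluefin tuna",
)


@dataclass
class AnalysisConfig:
    """Pipeline-wide thresholds and settings.

    Defaults reproduce the study's analysis settings: prey families below 1%
    mean proportional abundance are lumped into "Other" groups, stomachs whose
    reconstructed contents exceed 3% of predator body mass are excluded from
    energetic analyses, prey-specific metrics are reported for prey occurring
    in at least 20% of a group's stomachs, and a mean prey-specific proportion
    above 0.5 flags specialist feeding.
    """

    lump_threshold: float = 0.01
    bm_exclusion: float = 0.03
    fo_threshold: float = 0.20
    specialist_threshold: float = 0.5
    permutations: int = 999
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lump_threshold", "bm_exclusion", "fo_threshold", "specialist_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def with_updates(obj, **kwargs):
    """Dataclass-friendly copy-with-changes helper."""
    return replace(obj, **kwargs)
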
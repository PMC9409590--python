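"""Shared fixtures: small hand-built datasets and the three-regime fixture."""

import numpy as np
import pandas as pd
import pytest

from bluefin_diet.composition import build_diet_matrix, lump_rare_families, mean_proportional_abundance
from bluefin_diet.io import Dataset, EnergyResolver, RegressionResolver
from bluefin_diet.synth import three_regime_fixture
from bluefin_diet.types import (
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


@pytest.fixture(scope="session")
def fixture_dataset():
    """One deterministic three-regime synthetic dataset shared across tests."""
    return three_regime_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_diet_matrix(fixture_dataset):
    ds = fixture_dataset.dataset
    fbg = {t.family: t.broad_group for t in ds.taxa.values()}
    pbar = mean_proportional_abundance(build_diet_matrix(ds))
    group_map = lump_rare_families(pbar, fbg)
    return build_diet_matrix(ds, group_map)


@pytest.fixture(scope="session")
def fixture_covariates(fixture_dataset, fixture_diet_matrix):
    sf = fixture_dataset.dataset.stomach_frame().set_index("stomach_id")
    return sf[["year", "month", "lat", "lon", "fl_cm"]].loc[fixture_diet_matrix.index]


def make_taxon(taxon_id="taxA", broad_group="fish", family="FamA", genus=None, species=None):
    return PreyTaxon(taxon_id, BroadGroup(broad_group), family, genus, species)


def make_stomach(stomach_id, year, prey_specs, taxa, **kwargs):
    """prey_specs: list of (taxon_id, measurement_kind, value)."""
    rec = StomachRecord(stomach_id=stomach_id, year=year, **kwargs)
    for i, (taxon_id, kind, value) in enumerate(prey_specs):
        rec.prey.append(
            PreyItem(
                prey_id=f"{stomach_id}-p{i}",
                stomach_id=stomach_id,
                taxon_id=taxon_id,
                measurement_kind=MeasurementKind(kind),
                measured_value_mm=value,
            )
        )
    return rec


@pytest.fixture
def toy_dataset():
    """Three stomachs, two fish taxa and one cephalopod, hand-countable."""
    taxa = {
        "anchovy": make_taxon("anchovy", "fish", "Engraulidae", "Engraulis", "Engraulis mordax"),
        "lanternfish": make_taxon("lanternfish", "fish", "Myctophidae", "Triphoturus", "Triphoturus mexicanus"),
        "squid": make_taxon("squid", "cephalopod", "Enoploteuthidae", "Abraliopsis"),
    }
    records = [
        make_stomach("s1", 2008, [("anchovy", "whole_length", 80.0),
                                  ("anchovy", "unmeasured", None),
                                  ("lanternfish", "whole_length", 40.0)], taxa),
        make_stomach("s2", 2008, [("squid", "hard_part", 2.0)], taxa),
        make_stomach("s3", 2015, [("anchovy", "whole_length", 90.0),
                                  ("squid", "unmeasured", None),
                                  ("squid", "unmeasured", None),
                                  ("squid", "hard_part", 3.0)], taxa),
    ]
    return Dataset(records=records, taxa=taxa)


@pytest.fixture
def toy_resolver():
    specs = [
        RegressionSpec("family", "Enoploteuthidae", RegressionKind.HARDPART_TO_LENGTH,
                       RegressionForm.LINEAR, (0.0, 10.0)),
        RegressionSpec("broad_group", "fish", RegressionKind.LENGTH_TO_MASS,
                       RegressionForm.POWER, (0.01, 3.0), "mm", "g"),
        RegressionSpec("broad_group", "cephalopod", RegressionKind.LENGTH_TO_MASS,
                       RegressionForm.POWER, (0.02, 2.0), "mm", "g"),
        RegressionSpec("family", "Enoploteuthidae", RegressionKind.BEAK_TO_MASS,
                       RegressionForm.POWER, (0.02 * 10.0**2, 2.0), "mm", "g"),
        RegressionSpec("predator", "Thunnus orientalis", RegressionKind.OL_TO_FL,
                       RegressionForm.LINEAR, (0.0, 4.0), "cm", "cm"),
        RegressionSpec("predator", "Thunnus orientalis", RegressionKind.FL_TO_MASS,
                       RegressionForm.POWER, (2.0e-5, 3.0), "cm", "kg"),
    ]
    return RegressionResolver(specs)


@pytest.fixture
def toy_energy_resolver():
    return EnergyResolver(
        [
            EnergyDensity("species", "Engraulis mordax", 6.5),
            EnergyDensity("family", "Myctophidae", 8.0),
            EnergyDensity("broad_group", "cephalopod", 4.0),
        ]
    )
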
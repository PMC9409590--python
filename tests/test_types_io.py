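"""Domain types, CSV round-trips, resolver precedence, predator morphometrics."""

import math

import pytest

from bluefin_diet.io import (
    IntegrityError,
    RegressionResolver,
    SchemaError,
    derive_predator_size,
    read_dataset,
    read_energy_densities,
    read_regressions,
    write_dataset,
    write_energy_densities,
    write_regressions,
)
from bluefin_diet.synth import three_regime_fixture, write_synthetic_dataset
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

from conftest import make_stomach, make_taxon


class TestDomainTypes:
    def test_prey_item_measurement_consistency(self):
        with pytest.raises(ValueError, match="measured_value_mm"):
            PreyItem("p", "s", "t", MeasurementKind.WHOLE_LENGTH, None)
        with pytest.raises(ValueError, match="measured_value_mm"):
            PreyItem("p", "s", "t", MeasurementKind.UNMEASURED, 10.0)

    def test_empty_iff_no_nonbait_prey(self):
        rec = StomachRecord("s", 2010)
        assert rec.is_empty
        rec.prey.append(
            PreyItem("b", "s", "t", MeasurementKind.WHOLE_LENGTH, 120.0, is_bait=True)
        )
        assert rec.is_empty, "bait alone does not make a stomach non-empty"
        rec.prey.append(PreyItem("p", "s", "t", MeasurementKind.UNMEASURED, None))
        assert not rec.is_empty

    def test_family_always_populated(self):
        with pytest.raises(ValueError):
            PreyTaxon("x", BroadGroup.FISH, "")

    @pytest.mark.parametrize(
        "form,coeffs,x,expected",
        [
            (RegressionForm.LINEAR, (0.0, 4.0), 20.0, 80.0),
            (RegressionForm.POWER, (2.0e-5, 3.0), 100.0, 20.0),
            (RegressionForm.LOG_LINEAR, (-2.0, 2.0), 10.0, 1.0),
        ],
    )
    def test_regression_forms_and_inversion(self, form, coeffs, x, expected):
        spec = RegressionSpec("broad_group", "fish", RegressionKind.LENGTH_TO_MASS, form, coeffs)
        assert spec.predict(x) == pytest.approx(expected)
        assert spec.invert(spec.predict(x)) == pytest.approx(x)


class TestReadWrite:
    def test_round_trip_dataset(self, tmp_path):
        synth = three_regime_fixture(seed=11, n_stomachs=(5, 10, 5))
        paths = write_synthetic_dataset(synth, tmp_path)
        ds = read_dataset(paths["prey"], paths["stomachs"])
        orig = synth.dataset
        assert len(ds.records) == len(orig.records)
        for a, b in zip(
            sorted(ds.records, key=lambda r: r.stomach_id),
            sorted(orig.records, key=lambda r: r.stomach_id),
        ):
            assert a.stomach_id == b.stomach_id
            assert a.year == b.year
            assert len(a.prey) == len(b.prey)
            assert a.is_empty == b.is_empty
        # re-writing yields identical logical content
        paths2 = write_dataset(ds, tmp_path / "again")
        ds2 = read_dataset(paths2[1], paths2[0])
        assert ds2.prey_frame().equals(ds.prey_frame())

    def test_round_trip_parameter_tables(self, tmp_path):
        synth = three_regime_fixture(seed=11, n_stomachs=(2, 2, 2))
        write_regressions(synth.regressions, tmp_path / "r.csv")
        write_energy_densities(synth.energy_densities, tmp_path / "e.csv")
        rr = read_regressions(tmp_path / "r.csv")
        er = read_energy_densities(tmp_path / "e.csv")
        taxon = synth.dataset.taxa["engraulis_mordax"]
        orig = RegressionResolver(synth.regressions)
        for kind in (RegressionKind.LENGTH_TO_MASS, RegressionKind.HARDPART_TO_LENGTH):
            a, b = rr.resolve(taxon, kind), orig.resolve(taxon, kind)
            assert (a is None) == (b is None)
            if a is not None:
                assert a.coefficients == pytest.approx(b.coefficients)
        assert er.resolve(taxon).kj_per_g == pytest.approx(6.5)

    def test_unknown_stomach_reference_names_the_id(self, tmp_path):
        (tmp_path / "stomachs.csv").write_text(
            "stomach_id,year,month,lat,lon,fl_cm,ol_cm\ns1,2010,6,,,80,\n"
        )
        (tmp_path / "prey.csv").write_text(
            "prey_id,stomach_id,taxon_id,broad_group,family,genus,species,"
            "measurement_kind,measured_value_mm,is_bait\n"
            "p1,GHOST,t1,fish,FamA,,,unmeasured,,False\n"
        )
        with pytest.raises(IntegrityError, match="GHOST"):
            read_dataset(tmp_path / "prey.csv", tmp_path / "stomachs.csv")

    def test_duplicate_prey_id_rejected(self, tmp_path):
        (tmp_path / "stomachs.csv").write_text(
            "stomach_id,year,month,lat,lon,fl_cm,ol_cm\ns1,2010,6,,,80,\n"
        )
        (tmp_path / "prey.csv").write_text(
            "prey_id,stomach_id,taxon_id,broad_group,family,genus,species,"
            "measurement_kind,measured_value_mm,is_bait\n"
            "p1,s1,t1,fish,FamA,,,unmeasured,,False\n"
            "p1,s1,t1,fish,FamA,,,unmeasured,,False\n"
        )
        with pytest.raises(IntegrityError, match="duplicate"):
            read_dataset(tmp_path / "prey.csv", tmp_path / "stomachs.csv")

    def test_missing_column_is_schema_error(self, tmp_path):
        (tmp_path / "stomachs.csv").write_text("stomach_id,year\ns1,2010\n")
        (tmp_path / "prey.csv").write_text("prey_id\np1\n")
        with pytest.raises(SchemaError, match="missing required column"):
            read_dataset(tmp_path / "prey.csv", tmp_path / "stomachs.csv")


class TestResolverPrecedence:
    def _specs(self, levels):
        out = []
        for level, value in levels:
            out.append(
                RegressionSpec(
                    level, value, RegressionKind.LENGTH_TO_MASS,
                    RegressionForm.LINEAR, (float(len(out)), 1.0),
                )
            )
        return out

    def test_precedence_over_all_level_combinations(self):
        """Species beats genus beats family beats broad group, exhaustively."""
        taxon = make_taxon("t", "fish", "FamA", genus="GenA", species="SpA")
        level_values = [
            ("species", "SpA"), ("genus", "GenA"), ("family", "FamA"), ("broad_group", "fish"),
        ]
        for mask in range(1, 16):
            chosen = [lv for i, lv in enumerate(level_values) if mask >> i & 1]
            resolver = RegressionResolver(self._specs(chosen))
            hit = resolver.resolve(taxon, RegressionKind.LENGTH_TO_MASS)
            assert hit is not None
            assert hit.scope_level == chosen[0][0], f"mask {mask:04b}"

    def test_no_match_is_none_not_error(self):
        resolver = RegressionResolver(self._specs([("family", "FamB")]))
        taxon = make_taxon("t", "fish", "FamA")
        assert resolver.resolve(taxon, RegressionKind.LENGTH_TO_MASS) is None


class TestDerivePredatorSize:
    def test_fl_present_mass_filled_fl_unchanged(self, toy_resolver):
        rec = StomachRecord("s", 2010, fork_length_cm=100.0)
        rec = derive_predator_size(rec, toy_resolver)
        assert rec.fork_length_cm == 100.0
        assert rec.predator_mass_kg == pytest.approx(20.0)

    def test_ol_only_uses_linear_conversion(self, toy_resolver):
        rec = StomachRecord("s", 2010, operculum_length_cm=20.0)
        rec = derive_predator_size(rec, toy_resolver)
        assert rec.fork_length_cm == pytest.approx(80.0)
        assert rec.fl_estimated_from_ol

    def test_no_size_information_flags_not_raises(self, toy_resolver):
        rec = StomachRecord("s", 2010)
        rec = derive_predator_size(rec, toy_resolver)
        assert rec.predator_mass_kg is None
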
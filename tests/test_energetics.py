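"""Length reconstruction, hierarchical imputation, mass/energy, %BM filter."""

import numpy as np
import pandas as pd
import pytest

from bluefin_diet.energetics import (
    assign_energies,
    assign_masses,
    hardpart_to_length,
    impute_lengths,
    length_to_mass,
    reconstruct,
    reconstruct_lengths,
    stomach_totals_and_filter,
)
from bluefin_diet.io import Dataset, EnergyResolver, RegressionResolver
from bluefin_diet.types import (
    AnalysisConfig,
    LengthSource,
    MeasurementKind,
    PreyItem,
    RegressionForm,
    RegressionKind,
    RegressionSpec,
)

from conftest import make_stomach, make_taxon


class TestHardpartToLength:
    def test_linear_spec_forced_value(self, toy_dataset, toy_resolver):
        item = toy_dataset.record("s2").prey[0]  # squid beak, rostral 2.0 mm
        taxon = toy_dataset.taxa["squid"]
        assert hardpart_to_length(item, taxon, toy_resolver) == pytest.approx(20.0)

    def test_inversion_round_trip(self, toy_resolver):
        spec = toy_resolver.resolve(
            make_taxon("q", "cephalopod", "Enoploteuthidae"),
            RegressionKind.HARDPART_TO_LENGTH,
        )
        for true_length in (12.0, 33.3, 80.0):
            assert spec.predict(spec.invert(true_length)) == pytest.approx(true_length)

    def test_unidentified_squid_averages_all_beak_regressions(self):
        taxa = {
            "unid": make_taxon("unid", "cephalopod", "Unidentified cephalopods"),
            "a": make_taxon("a", "cephalopod", "FamA"),
            "b": make_taxon("b", "cephalopod", "FamB"),
        }
        resolver = RegressionResolver(
            [
                RegressionSpec("family", "FamA", RegressionKind.HARDPART_TO_LENGTH,
                               RegressionForm.LINEAR, (0.0, 10.0)),
                RegressionSpec("family", "FamB", RegressionKind.HARDPART_TO_LENGTH,
                               RegressionForm.LINEAR, (0.0, 20.0)),
            ]
        )
        item = PreyItem("p", "s", "unid", MeasurementKind.HARD_PART, 2.0)
        # mean of 20 and 40
        assert hardpart_to_length(item, taxa["unid"], resolver, taxa) == pytest.approx(30.0)


class TestImputation:
    def _dataset(self, specs_by_stomach):
        taxa = {"fishA": make_taxon("fishA", "fish", "FamA", "GenA", "SpA")}
        records = [
            make_stomach(sid, year, specs, taxa)
            for sid, year, specs in specs_by_stomach
        ]
        return Dataset(records=records, taxa=taxa)

    def test_all_measured_unchanged(self, toy_resolver):
        ds = self._dataset(
            [("s1", 2010, [("fishA", "whole_length", 50.0)])]
        )
        reconstruct_lengths(ds, toy_resolver)
        impute_lengths(ds, {"s1": "g"})
        item = ds.record("s1").prey[0]
        assert item.length_mm == 50.0
        assert item.length_source == LengthSource.MEASURED

    def test_stomach_mean_of_two(self, toy_resolver):
        ds = self._dataset(
            [
                (
                    "s1", 2010,
                    [("fishA", "whole_length", 40.0),
                     ("fishA", "whole_length", 60.0),
                     ("fishA", "unmeasured", None)],
                )
            ]
        )
        reconstruct_lengths(ds, toy_resolver)
        impute_lengths(ds, {"s1": "g"})
        item = ds.record("s1").prey[2]
        assert item.length_mm == pytest.approx(50.0)
        assert item.length_source == LengthSource.IMPUTED_STOMACH

    @pytest.mark.parametrize("pattern", range(8))
    def test_precedence_exhaustive_over_presence_patterns(self, pattern, toy_resolver):
        """Oracle over all 8 presence/absence combinations of the 3 levels.

        Level values are distinct (stomach 50, year 70, group 90) so the
        assigned mean identifies which pool was used.
        """
        has_stomach, has_year, has_group = (pattern >> i & 1 for i in range(3))
        records = [("s0", 2010, [("fishA", "unmeasured", None)])]
        if has_stomach:
            records[0] = ("s0", 2010, [("fishA", "unmeasured", None),
                                       ("fishA", "whole_length", 50.0)])
        if has_year:
            records.append(("s_year", 2010, [("fishA", "whole_length", 70.0)]))
        if has_group:
            records.append(("s_group", 1999, [("fishA", "whole_length", 90.0)]))
        ds = self._dataset(records)
        grouping = {sid: "g" for sid, _, _ in records}
        reconstruct_lengths(ds, toy_resolver)
        impute_lengths(ds, grouping)
        item = ds.record("s0").prey[0]

        # independent oracle: first non-empty of stomach -> year -> group
        if has_stomach:
            expected, source = 50.0, LengthSource.IMPUTED_STOMACH
        elif has_year:
            expected, source = 70.0, LengthSource.IMPUTED_YEAR
        elif has_group:
            expected, source = 90.0, LengthSource.IMPUTED_GROUP
        else:
            expected, source = None, None
        if expected is None:
            assert item.length_mm is None, "unresolvable prey must stay lengthless"
        else:
            assert item.length_mm == pytest.approx(expected)
            assert item.length_source == source

    def test_year_pool_includes_own_and_other_stomachs(self, toy_resolver):
        """Year-level mean pools all measured conspecifics from that year."""
        ds = self._dataset(
            [
                ("s1", 2010, [("fishA", "unmeasured", None)]),
                ("s2", 2010, [("fishA", "whole_length", 60.0)]),
                ("s3", 2010, [("fishA", "whole_length", 80.0)]),
            ]
        )
        reconstruct_lengths(ds, toy_resolver)
        impute_lengths(ds, {s: "g" for s in ("s1", "s2", "s3")})
        assert ds.record("s1").prey[0].length_mm == pytest.approx(70.0)

    def test_unidentified_uses_broad_group_fallback(self, toy_resolver):
        taxa = {
            "unidf": make_taxon("unidf", "fish", "Unidentified fishes"),
            "fishA": make_taxon("fishA", "fish", "FamA", "GenA", "SpA"),
        }
        records = [
            make_stomach("s1", 2010, [("unidf", "unmeasured", None)], taxa),
            make_stomach("s2", 2010, [("fishA", "whole_length", 44.0)], taxa),
        ]
        ds = Dataset(records=records, taxa=taxa)
        reconstruct_lengths(ds, toy_resolver)
        impute_lengths(ds, {"s1": "g", "s2": "g"})
        item = ds.record("s1").prey[0]
        assert item.length_mm == pytest.approx(44.0)
        assert item.length_source == LengthSource.IMPUTED_FALLBACK


class TestMassAndEnergy:
    def test_power_law_hand_value(self, toy_dataset, toy_resolver):
        # fish length->mass a=0.01, b=3: 10 mm -> 10 g
        item = PreyItem("p", "s", "anchovy", MeasurementKind.WHOLE_LENGTH, 10.0)
        item.length_mm = 10.0
        mass = length_to_mass(item, toy_dataset.taxa["anchovy"], toy_resolver)
        assert mass == pytest.approx(10.0)

    def test_cephalopod_beak_route_bypasses_length(self, toy_dataset, toy_resolver):
        item = PreyItem("p", "s", "squid", MeasurementKind.HARD_PART, 2.0)
        item.length_mm = 999.0  # would give a wildly different mass
        mass = length_to_mass(item, toy_dataset.taxa["squid"], toy_resolver)
        # beak_to_mass = 0.02*10^2 * x^2 = 2 * 4 = 8
        assert mass == pytest.approx(8.0)

    def test_non_positive_length_guard(self, toy_dataset, toy_resolver):
        item = PreyItem("p", "s", "anchovy", MeasurementKind.UNMEASURED, None)
        item.length_mm = -5.0
        with pytest.raises(ValueError):
            length_to_mass(item, toy_dataset.taxa["anchovy"], toy_resolver)

    def test_energy_simple_and_family_fallback(self, toy_dataset, toy_resolver, toy_energy_resolver):
        ds = toy_dataset
        reconstruct_lengths(ds, toy_resolver)
        impute_lengths(ds, {s: "g" for s in ("s1", "s2", "s3")})
        assign_masses(ds, toy_resolver)
        assign_energies(ds, toy_energy_resolver, {s: "g" for s in ("s1", "s2", "s3")})
        anchovy = ds.record("s1").prey[0]
        assert anchovy.energy_kj == pytest.approx(anchovy.mass_g * 6.5)
        lantern = ds.record("s1").prey[2]  # no species-level density, family 8.0
        assert lantern.energy_kj == pytest.approx(lantern.mass_g * 8.0)

    def test_unidentified_energy_is_year_mean_of_identified(self, toy_resolver):
        taxa = {
            "unidf": make_taxon("unidf", "fish", "Unidentified fishes"),
            "f1": make_taxon("f1", "fish", "FamA", "G", "Sp1"),
            "f2": make_taxon("f2", "fish", "FamB", "G", "Sp2"),
        }
        from bluefin_diet.types import EnergyDensity
        er = EnergyResolver(
            [EnergyDensity("species", "Sp1", 4.0), EnergyDensity("species", "Sp2", 6.0)]
        )
        records = [
            make_stomach("s1", 2010, [("unidf", "whole_length", 10.0),
                                      ("f1", "whole_length", 10.0),
                                      ("f2", "whole_length", 10.0)], taxa),
        ]
        ds = Dataset(records=records, taxa=taxa)
        reconstruct_lengths(ds, toy_resolver)
        assign_masses(ds, toy_resolver)
        assign_energies(ds, er, {"s1": "g"})
        unid = ds.record("s1").prey[0]
        assert unid.energy_kj == pytest.approx(unid.mass_g * 5.0)  # mean of 4 and 6


class TestBodyMassFilter:
    def _dataset_with_mass(self, predator_kg, content_g):
        taxa = {"fishA": make_taxon("fishA", "fish", "FamA", "GenA", "SpA")}
        rec = make_stomach("s1", 2010, [("fishA", "whole_length", 10.0)], taxa)
        rec.predator_mass_kg = predator_kg
        rec.prey[0].mass_g = content_g
        return Dataset(records=[rec], taxa=taxa)

    @pytest.mark.parametrize(
        "content_g,expected_bm,excluded",
        [(350.0, 3.5, True), (250.0, 2.5, False), (300.0, 3.0, False)],
    )
    def test_three_percent_rule_is_strict(self, content_g, expected_bm, excluded):
        ds = self._dataset_with_mass(10.0, content_g)
        totals, kept = stomach_totals_and_filter(ds, AnalysisConfig())
        row = totals.iloc[0]
        assert row["pct_body_mass"] == pytest.approx(expected_bm)
        assert row["excluded"] == excluded
        assert ("s1" in kept) != excluded

    def test_no_predator_mass_is_its_own_category(self):
        ds = self._dataset_with_mass(None, 100.0)
        totals, kept = stomach_totals_and_filter(ds)
        assert totals.iloc[0]["exclusion_reason"] == "no_predator_mass"
        assert kept == []

    def test_totals_are_additive(self, fixture_dataset):
        """Stomach totals equal the sum over constituent prey, and the
        filtered + excluded sets partition the whole."""
        import copy

        synth = fixture_dataset
        ds = copy.deepcopy(synth.dataset)
        grouping = {r.stomach_id: synth.regime_of[r.stomach_id] for r in ds.non_empty()}
        totals, kept = reconstruct(
            ds,
            RegressionResolver(synth.regressions),
            EnergyResolver(synth.energy_densities),
            grouping,
        )
        by_hand = {}
        for rec in ds.non_empty():
            by_hand[rec.stomach_id] = sum(
                p.mass_g for p in rec.diet_items if p.mass_g is not None
            )
        merged = totals.set_index("stomach_id")
        for sid, expected in by_hand.items():
            if not np.isnan(merged.loc[sid, "total_mass_g"]):
                assert merged.loc[sid, "total_mass_g"] == pytest.approx(expected)
        assert set(kept) | set(merged.index[merged["excluded"]]) == set(merged.index)


class TestRecovery:
    def test_exact_recovery_when_fully_measured(self):
        from bluefin_diet.synth import three_regime_fixture

        synth = three_regime_fixture(seed=5, measured_fraction=1.0)
        ds = synth.dataset
        grouping = {r.stomach_id: synth.regime_of[r.stomach_id] for r in ds.non_empty()}
        totals, _ = reconstruct(
            ds, RegressionResolver(synth.regressions),
            EnergyResolver(synth.energy_densities), grouping,
        )
        truth = synth.truth.groupby("stomach_id")["true_energy_kj"].sum()
        merged = totals.set_index("stomach_id").join(truth)
        assert merged["total_energy_kj"].notna().all()
        err = (merged["total_energy_kj"] - merged["true_energy_kj"]).abs()
        assert err.max() < 1e-9

    def test_half_measured_tight_lengths_within_ten_percent(self):
        from bluefin_diet.synth import DEFAULT_LENGTH_PARAMS, default_regimes, generate_dataset

        tight = {k: (mu, 0.15) for k, (mu, _) in DEFAULT_LENGTH_PARAMS.items()}
        regimes = default_regimes(measured_fraction=0.5, length_params=tight)
        synth = generate_dataset(regimes, seed=6)
        ds = synth.dataset
        grouping = {r.stomach_id: synth.regime_of[r.stomach_id] for r in ds.non_empty()}
        totals, _ = reconstruct(
            ds, RegressionResolver(synth.regressions),
            EnergyResolver(synth.energy_densities), grouping,
        )
        truth = synth.truth.groupby("stomach_id")["true_energy_kj"].sum()
        merged = totals.set_index("stomach_id").join(truth)
        rel = ((merged["total_energy_kj"] - merged["true_energy_kj"]) / merged["true_energy_kj"]).abs()
        assert rel.median() <= 0.10
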
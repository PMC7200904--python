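"""Marker-ratio digestibility, DE/ME calculus, and the difference method."""

import pytest

from feedval.energy_balance import (
    CollectionRecord,
    EnergyBalanceError,
    EnergyValues,
    UndefinedDigestibilityError,
    collection_records_to_df,
    diet_energy,
    feed_allowance,
    ingredient_energy_by_difference,
    marker_digestibility,
    read_collection_records_csv,
)
from feedval.simulate import recover_diet_energy, simulate_energy_trial


class TestMarkerDigestibility:
    def test_nothing_in_output_means_fully_digested(self):
        assert marker_digestibility(4.0, 0.0, 0.2, 0.4) == 1.0

    def test_unchanged_concentrations_mean_zero_digestion(self):
        assert marker_digestibility(4.0, 4.0, 0.21, 0.21) == 0.0

    def test_marker_doubling_with_halved_nutrient(self):
        assert marker_digestibility(4.0, 2.0, 0.21, 0.42) == pytest.approx(0.75)

    def test_negative_when_output_enriched(self):
        # endogenous secretion can push the output above the diet level
        assert marker_digestibility(1.0, 3.0, 0.2, 0.4) < 0

    @pytest.mark.parametrize(
        "kwargs",
        [dict(conc_diet=0.0), dict(marker_output=0.0), dict(marker_diet=0.0)],
    )
    def test_zero_denominators_rejected(self, kwargs):
        base = dict(conc_diet=4.0, conc_output=2.0, marker_diet=0.2, marker_output=0.4)
        base.update(kwargs)
        with pytest.raises(UndefinedDigestibilityError):
            marker_digestibility(**base)


def record(**kw):
    base = dict(
        pig_id="p1", diet="d", feed_intake=1.0, diet_dm_frac=0.9,
        fecal_output=0.15, fecal_ge=4000.0, urine_volume=2.0, urine_ge=50.0,
        ti_diet=0.25, ti_feces=1.5,
    )
    base.update(kw)
    return CollectionRecord(**base)


class TestDietEnergy:
    def test_no_excreted_energy_means_de_equals_ge(self):
        rec = record(fecal_ge=0.0, urine_ge=0.0)
        for method in ("marker", "total"):
            e = diet_energy(rec, 4400.0, method=method)
            assert e.de == e.me == 4400.0

    def test_noise_free_records_recover_diet_truth(self, clean_scenario):
        sc = clean_scenario
        records = simulate_energy_trial(sc)
        for method in ("marker", "total"):
            est = recover_diet_energy(records, {d.name: d.ge for d in sc.energy_diets},
                                      method=method)
            for d in sc.energy_diets:
                assert est[d.name].de == pytest.approx(d.de, abs=1e-9)
                assert est[d.name].me == pytest.approx(d.me, abs=1e-9)

    def test_corn_diet_me_de_ratio(self, clean_scenario):
        # the basal corn diet loses little energy in urine: ME:DE near 0.98
        sc = clean_scenario
        est = recover_diet_energy(
            simulate_energy_trial(sc), {d.name: d.ge for d in sc.energy_diets}
        )
        assert est["control"].me_de == pytest.approx(0.9865, abs=0.01)

    def test_zero_intake_rejected(self):
        with pytest.raises(EnergyBalanceError):
            diet_energy(record(feed_intake=0.0), 4400.0)

    def test_me_cannot_exceed_de(self):
        with pytest.raises(EnergyBalanceError):
            EnergyValues(de=3000.0, me=3100.0)

    def test_excessive_urinary_energy_rejected(self):
        with pytest.raises(EnergyBalanceError):
            diet_energy(record(urine_ge=1e6), 4400.0)

    def test_marker_below_diet_level_warns(self):
        with pytest.warns(UserWarning, match="marker"):
            record(ti_feces=0.1)


class TestDifferenceMethod:
    F_BT, F_BB, F_TEST = 0.669, 0.969, 0.30

    def test_identical_diets_scale_algebraically(self):
        basal = EnergyValues(de=4000.0, me=3900.0)
        ing = ingredient_energy_by_difference(basal, basal, self.F_BT, self.F_BB, self.F_TEST)
        scale = (1 - self.F_BT / self.F_BB) / self.F_TEST  # ~1.032
        assert ing.de == pytest.approx(scale * basal.de, rel=1e-12)

    def test_zero_energy_ingredient(self):
        basal = EnergyValues(de=4000.0, me=4000.0)
        test = EnergyValues(de=4000.0 * self.F_BT / self.F_BB, me=4000.0 * self.F_BT / self.F_BB)
        ing = ingredient_energy_by_difference(test, basal, self.F_BT, self.F_BB, self.F_TEST)
        assert ing.de == pytest.approx(0.0, abs=1e-9)

    def test_recovers_ingredient_truth_from_noise_free_trial(self, clean_scenario):
        from feedval.simulate import recover_ingredient_energy

        sc = clean_scenario
        est = recover_ingredient_energy(sc, simulate_energy_trial(sc))
        for name in ("FW", "SMW", "FVW"):
            assert est[name].de == pytest.approx(sc.ingredient_truth[name]["de"], abs=1.0)
            assert est[name].me == pytest.approx(sc.ingredient_truth[name]["me"], abs=1.0)

    def test_zero_inclusion_rejected(self):
        basal = EnergyValues(de=4000.0, me=3900.0)
        with pytest.raises(ValueError):
            ingredient_energy_by_difference(basal, basal, 0.669, 0.969, 0.0)


class TestFeedAllowance:
    def test_unit_body_weight(self):
        assert feed_allowance(1.0) == pytest.approx(591.0)

    def test_trial_entry_weight(self):
        assert feed_allowance(16.37) == pytest.approx(3162.4, abs=0.1)

    def test_power_law_scaling(self):
        assert feed_allowance(20.0) / feed_allowance(10.0) == pytest.approx(2 ** 0.6)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            feed_allowance(0.0)


def test_collection_record_csv_round_trip(tmp_path, clean_scenario):
    records = simulate_energy_trial(clean_scenario)[:5]
    path = tmp_path / "records.csv"
    collection_records_to_df(records).to_csv(path, index=False)
    assert read_collection_records_csv(path) == records
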
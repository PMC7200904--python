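"""Prediction-equation registry: published-table reproduction and contracts."""

import math

import pytest

from feedval.composition import Basis, IngredientComposition, MissingInputError
from feedval.prediction import (
    EQUATIONS,
    KCAL_PER_MJ,
    mj_to_kcal,
    predict,
    predict_all,
)

# Printed predictions (kcal/kg DM) per (equation, ingredient); the override
# flag marks fish-waste rows of the chemical-composition family, which were
# published with the NDF term at zero.  The published integers carry the
# authors' intermediate rounding, so agreement is asserted to within 1 kcal.
PRINTED = [
    # chemical-composition DE
    ("1", "SMW", False, 4796), ("1", "FVW", False, 2731), ("1", "FW", True, 5234),
    ("2", "SMW", False, 4831), ("2", "FVW", False, 2736), ("2", "FW", True, 4517),
    ("3", "SMW", False, 4909), ("3", "FVW", False, 2786), ("3", "FW", True, 4605),
    # chemical-composition ME
    ("4", "SMW", False, 4759), ("4", "FVW", False, 2749), ("4", "FW", True, 4090),
    # stepwise-regression DE
    ("8", "FW", False, 5566), ("8", "SMW", False, 5490), ("8", "FVW", False, 2727),
    ("9", "FW", False, 4017), ("9", "SMW", False, 3502), ("9", "FVW", False, -66),
    ("10", "FW", False, 3991), ("10", "SMW", False, 5053), ("10", "FVW", False, 4931),
    ("11", "FW", False, 4104), ("11", "SMW", False, 3961), ("11", "FVW", False, 1019),
    # stepwise-regression ME
    ("12", "FW", False, 5001), ("12", "SMW", False, 4932), ("12", "FVW", False, 2410),
    ("13", "FW", False, 3700), ("13", "SMW", False, 3557), ("13", "FVW", False, 52),
    ("14", "FW", False, 3624), ("14", "SMW", False, 4644), ("14", "FVW", False, 4526),
    ("15", "FW", False, 3725), ("15", "SMW", False, 3836), ("15", "FVW", False, 1395),
]


@pytest.mark.parametrize("eq_id, ingredient, zero_ndf, expected", PRINTED)
def test_published_predictions_reproduce(ingredients, eq_id, ingredient, zero_ndf, expected):
    out = predict(eq_id, ingredients[ingredient], zero_ndf=zero_ndf)
    assert out.predicted == pytest.approx(expected, abs=1.0)


def test_fish_waste_with_analyzed_ndf_differs(ingredients):
    # without the override the fiber term shifts the answer by ~170 kcal
    out = predict("1", ingredients["FW"])
    assert out.predicted == pytest.approx(5065, abs=1.0)
    assert abs(out.predicted - 5234) > 100


def test_override_is_recorded(ingredients):
    assert "NDF" in predict("1", ingredients["FW"], zero_ndf=True).notes


def test_me_equations_subtract_protein_correction(ingredients):
    # ME forms of the chemical family are DE minus 0.68 x CP (g/kg DM)
    for de_id, me_id in (("1", "5"), ("2", "6"), ("3", "7")):
        for name in ("SMW", "FVW"):
            comp = ingredients[name]
            cp_gkg = comp.cp / comp.dm_frac * 10.0
            assert predict(me_id, comp).predicted == pytest.approx(
                predict(de_id, comp).predicted - 0.68 * cp_gkg, rel=1e-12
            )


def test_equations_are_affine(ingredients):
    # doubling ash moves the ash-only regression by exactly its slope
    smw = ingredients["SMW"]
    p1 = predict("10", smw).predicted
    import dataclasses
    p2 = predict("10", dataclasses.replace(smw, ash=smw.ash * 2)).predicted
    assert p2 - p1 == pytest.approx(-87.5 * smw.ash / smw.dm_frac, rel=1e-9)


class TestUnits:
    def test_mj_conversion_constant(self):
        assert mj_to_kcal(0.0) == 0.0
        assert mj_to_kcal(1.0) == 238.834
        assert mj_to_kcal(20.9) == pytest.approx(4991.6, abs=0.05)

    def test_invitro_equations_convert_from_mj(self, ingredients):
        out = predict("16", ingredients["FVW"], omdv=800.0)
        assert out.predicted == pytest.approx(0.0189 * 800.0 * KCAL_PER_MJ, rel=1e-12)

    def test_invitro_equation_with_fiber_inputs(self, ingredients):
        out = predict("18", ingredients["SMW"], omdv=750.0, crude_fiber=2.0)
        ee_gkg = ingredients["SMW"].ee / ingredients["SMW"].dm_frac * 10.0
        mj = 5.02 + 0.0127 * 750.0 + 0.0172 * ee_gkg - 0.0124 * 20.0
        assert out.predicted == pytest.approx(mj * KCAL_PER_MJ, rel=1e-12)


class TestErrors:
    def test_missing_ndf_is_named(self):
        comp = IngredientComposition("x", Basis.DM, 1.0, ge=4000.0, cp=10.0,
                                     ee=5.0, ash=3.0, ndf=None)
        with pytest.raises(MissingInputError, match="ndf"):
            predict("1", comp)

    def test_missing_omdv_is_named(self, ingredients):
        with pytest.raises(MissingInputError, match="omdv"):
            predict("16", ingredients["SMW"])

    def test_unknown_equation_id(self, ingredients):
        with pytest.raises(KeyError):
            predict("42", ingredients["SMW"])

    def test_degenerate_zero_ge_flagged(self):
        comp = IngredientComposition("x", Basis.DM, 1.0, ge=0.0)
        out = predict("12", comp)
        assert out.predicted == pytest.approx(-2331.0)
        assert "negative" in out.notes


class TestBatch:
    def test_one_row_per_pair(self, ingredients):
        comps = [ingredients["SMW"], ingredients["FVW"]]
        df = predict_all(comps, eq_ids=["1", "2", "3"])
        assert len(df) == 6
        assert set(df["ingredient"]) == {"SMW", "FVW"}

    def test_missing_inputs_reported_not_dropped(self, ingredients):
        df = predict_all([ingredients["SMW"]], eq_ids=["16"])  # no OMdv given
        assert len(df) == 1
        assert math.isnan(df.loc[0, "predicted"])
        assert "omdv" in df.loc[0, "notes"]

    def test_empty_equation_list(self, ingredients):
        assert predict_all([ingredients["SMW"]], eq_ids=[]).empty

    def test_unknown_id_raises(self, ingredients):
        with pytest.raises(KeyError):
            predict_all([ingredients["SMW"]], eq_ids=["nope"])

    def test_registry_covers_all_published_equations(self):
        assert set(EQUATIONS) == {str(i) for i in range(1, 20)}
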
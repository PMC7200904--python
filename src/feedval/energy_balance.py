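"""Energy-balance calculus of the total-collection trial.

A growing pig housed in a metabolism crate eats a known mass of diet;
feces and urine are collected quantitatively.  Digestible energy (DE) is
gross energy (GE) intake minus fecal energy, and metabolizable energy
(ME) further subtracts urinary energy, both expressed per kg of dietary
dry matter (DM).  Because complete fecal collection is laborious and
error-prone, an inert dietary marker (titanium dioxide) offers an
alternative: any nutrient's apparent digestibility follows from how much
the marker concentrates between diet and excreta.  Both estimators are
implemented; on a mass-balanced record they agree exactly.

An ingredient fed at partial inclusion is valued by the *difference
method*: the basal diet's contribution is subtracted from the test
diet's energy value and the remainder attributed to the test ingredient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional


class UndefinedDigestibilityError(ZeroDivisionError):
    """Marker or diet concentration of zero makes the ratio undefined."""


class EnergyBalanceError(ValueError):
    """A collection record violates the DE/ME energy ordering."""


def marker_digestibility(
    conc_diet: float,
    conc_output: float,
    marker_diet: float,
    marker_output: float,
) -> float:
    """Apparent digestibility of a nutrient from the indigestible-marker ratio.

    Returns ``1 - (marker_diet/marker_output) * (conc_output/conc_diet)``,
    the fraction of the nutrient that disappeared between diet and output
    (feces or ileal digesta).  Diet and output concentrations must share a
    basis (conventionally % of DM or g/kg DM).  The value may be negative:
    endogenous secretion can make a nutrient *more* concentrated in the
    output than marker dilution alone predicts, as observed for the amino
    acids of fibrous feedstuffs.
    """
    if marker_output <= 0 or conc_diet <= 0 or marker_diet <= 0:
        raise UndefinedDigestibilityError(
            "marker and diet concentrations must be positive "
            f"(marker_diet={marker_diet}, marker_output={marker_output}, "
            f"conc_diet={conc_diet})"
        )
    if conc_output < 0:
        raise UndefinedDigestibilityError(f"conc_output={conc_output} < 0")
    return 1.0 - (marker_diet / marker_output) * (conc_output / conc_diet)


@dataclass(frozen=True)
class CollectionRecord:
    """One pig-period of a total-collection digestibility trial.

    Masses and volumes are daily averages over the collection period.
    ``fecal_nutrients`` holds analyzed fecal concentrations (% of fecal
    DM) for whatever nutrients the trial measures (e.g. ``"P"``).
    """

    pig_id: str
    diet: str
    feed_intake: float          # kg as-fed / day
    diet_dm_frac: float         # DM fraction of the diet
    fecal_output: float         # kg DM / day
    fecal_ge: float             # kcal / kg fecal DM
    urine_volume: float = 0.0   # L / day
    urine_ge: float = 0.0       # kcal / L
    ti_diet: Optional[float] = None    # marker, % of diet DM
    ti_feces: Optional[float] = None   # marker, % of fecal DM
    fecal_nutrients: Mapping[str, float] = field(default_factory=dict)
    bw: Optional[float] = None  # kg, informational

    def __post_init__(self):
        for fname in ("feed_intake", "fecal_output", "fecal_ge", "urine_volume", "urine_ge"):
            v = getattr(self, fname)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{self.pig_id}: {fname} must be finite and >= 0, got {v}")
        if not (0.0 < self.diet_dm_frac <= 1.0):
            raise ValueError(f"{self.pig_id}: diet_dm_frac out of (0, 1]")
        # The marker concentrates in feces for any animal digesting DM; the
        # reverse indicates an assay or transcription problem, not impossibility.
        if (
            self.ti_diet is not None
            and self.ti_feces is not None
            and self.ti_feces < self.ti_diet
        ):
            warnings.warn(
                f"{self.pig_id}/{self.diet}: fecal marker ({self.ti_feces}) below "
                f"dietary marker ({self.ti_diet}); check the record",
                stacklevel=2,
            )

    @property
    def dm_intake(self) -> float:
        """Dietary DM intake, kg/day."""
        return self.feed_intake * self.diet_dm_frac


@dataclass(frozen=True)
class EnergyValues:
    """DE and ME of a diet or ingredient, kcal/kg DM, with energy ratios."""

    de: float
    me: float
    ge: Optional[float] = None

    def __post_init__(self):
        if self.me > self.de + 1e-9:
            raise EnergyBalanceError(f"ME ({self.me}) exceeds DE ({self.de})")
        if self.ge is not None and self.de > self.ge + 1e-9:
            raise EnergyBalanceError(f"DE ({self.de}) exceeds GE ({self.ge})")

    @property
    def de_ge(self) -> Optional[float]:
        return None if self.ge is None else self.de / self.ge

    @property
    def me_ge(self) -> Optional[float]:
        return None if self.ge is None else self.me / self.ge

    @property
    def me_de(self) -> float:
        return self.me / self.de


def diet_energy(
    rec: CollectionRecord, diet_ge: float, method: str = "marker"
) -> EnergyValues:
    """DE and ME of a diet (kcal/kg DM) from one collection record.

    Parameters
    ----------
    rec : CollectionRecord
    diet_ge : float
        Gross energy of the diet, kcal/kg DM.
    method : {"marker", "total"}
        ``"marker"`` infers GE digestibility from the titanium ratio
        between diet and feces; ``"total"`` uses the collected fecal mass
        directly.  Urinary energy is always taken from total collection.
    """
    dmi = rec.dm_intake
    if dmi <= 0:
        raise EnergyBalanceError(f"{rec.pig_id}: zero DM intake")
    if method == "marker":
        if rec.ti_diet is None or rec.ti_feces is None:
            raise EnergyBalanceError(f"{rec.pig_id}: marker concentrations missing")
        ge_dig = marker_digestibility(diet_ge, rec.fecal_ge, rec.ti_diet, rec.ti_feces)
        de = diet_ge * ge_dig
    elif method == "total":
        de = (dmi * diet_ge - rec.fecal_output * rec.fecal_ge) / dmi
    else:
        raise ValueError(f"unknown method {method!r}")
    me = de - rec.urine_volume * rec.urine_ge / dmi
    if me <= 0:
        raise EnergyBalanceError(f"{rec.pig_id}: nonpositive ME ({me:.1f})")
    return EnergyValues(de=de, me=me, ge=diet_ge)


def ingredient_energy_by_difference(
    test_diet: EnergyValues,
    basal_diet: EnergyValues,
    basal_frac_in_test: float,
    basal_frac_in_basal: float,
    test_frac: float,
    ingredient_ge: Optional[float] = None,
) -> EnergyValues:
    """Energy value of a test ingredient by the difference method.

    The test diet replaces part of the basal diet's energy-yielding base
    with the ingredient (here 66.9% vs 96.9% corn at 30% inclusion), the
    shared minor ingredients (minerals, premix, marker) being identical
    across diets and assumed energy-neutral.  Then

        DE_ingredient = [DE_test - (f_bt / f_bb) * DE_basal] / f_test

    and identically for ME, with ``f_bt``/``f_bb`` the basal-base
    fractions in the test and basal diets and ``f_test`` the ingredient
    inclusion.  Pass ``ingredient_ge`` (kcal/kg DM) to populate the
    energy ratios of the result.
    """
    if test_frac <= 0:
        raise ValueError("test_frac must be positive")
    scale = basal_frac_in_test / basal_frac_in_basal
    de = (test_diet.de - scale * basal_diet.de) / test_frac
    me = (test_diet.me - scale * basal_diet.me) / test_frac
    return EnergyValues(de=de, me=me, ge=ingredient_ge)


def collection_records_to_df(records: "list[CollectionRecord]"):
    """Tabulate collection records; fecal nutrient assays become
    ``fecal_<nutrient>_pct`` columns."""
    import pandas as pd

    nutrients = sorted({n for r in records for n in r.fecal_nutrients})
    rows = []
    for r in records:
        row = {
            "pig_id": r.pig_id, "diet": r.diet, "bw_kg": r.bw,
            "feed_intake_kg": r.feed_intake, "diet_dm_frac": r.diet_dm_frac,
            "fecal_output_kg_dm": r.fecal_output, "fecal_ge_kcal_kg": r.fecal_ge,
            "urine_volume_l": r.urine_volume, "urine_ge_kcal_l": r.urine_ge,
            "ti_diet_pct": r.ti_diet, "ti_feces_pct": r.ti_feces,
        }
        for n in nutrients:
            row[f"fecal_{n}_pct"] = r.fecal_nutrients.get(n)
        rows.append(row)
    return pd.DataFrame(rows)


def read_collection_records_csv(path) -> "list[CollectionRecord]":
    """Read collection records written by :func:`collection_records_to_df`."""
    import pandas as pd

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    nutrient_cols = {
        c: c[len("fecal_"):-len("_pct")]
        for c in df.columns
        if c.startswith("fecal_") and c.endswith("_pct") and c != "fecal_output_kg_dm"
    }
    records = []
    for _, row in df.iterrows():
        records.append(
            CollectionRecord(
                pig_id=str(row["pig_id"]),
                diet=str(row["diet"]),
                feed_intake=float(row["feed_intake_kg"]),
                diet_dm_frac=float(row["diet_dm_frac"]),
                fecal_output=float(row["fecal_output_kg_dm"]),
                fecal_ge=float(row["fecal_ge_kcal_kg"]),
                urine_volume=float(row.get("urine_volume_l", 0.0) or 0.0),
                urine_ge=float(row.get("urine_ge_kcal_l", 0.0) or 0.0),
                ti_diet=None if pd.isna(row.get("ti_diet_pct")) else float(row["ti_diet_pct"]),
                ti_feces=None if pd.isna(row.get("ti_feces_pct")) else float(row["ti_feces_pct"]),
                fecal_nutrients={
                    n: float(row[c]) for c, n in nutrient_cols.items() if pd.notna(row[c])
                },
                bw=None if pd.isna(row.get("bw_kg")) else float(row["bw_kg"]),
            )
        )
    return records


def feed_allowance(
    bw: float, maintenance_kcal: float = 197.0, multiple: float = 3.0
) -> float:
    """Daily ME allowance, kcal/day, from metabolic body weight.

    Growing pigs are fed a multiple (default 3x) of the maintenance
    requirement of 197 kcal ME per kg of BW^0.60.
    """
    if bw <= 0:
        raise ValueError(f"body weight must be positive, got {bw}")
    return multiple * maintenance_kcal * bw ** 0.60
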
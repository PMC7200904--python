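"""Apparent and standardized digestibility of phosphorus and amino acids.

Apparent digestibility (total-tract ATTD, or ileal AID measured at a
T-cannula) counts every gram of a nutrient in the excreta against the
diet, including material the animal itself secreted.  The standardized
coefficients (STTD, SID) credit back a *basal endogenous loss* that is
independent of the diet: a fixed 190 mg P per kg DM intake for
phosphorus, and amino-acid flows measured in pigs fed a nitrogen-free
diet for the ileal coefficients.  The correction is additive, so the
standardized value always sits at or above the apparent one, may exceed
100% when endogenous flow dominates the dietary supply (proline and
glycine, classically), and inherits negative apparent values unchanged.

Per-pig coefficients are computed first and then averaged: the pig is
the experimental unit.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .composition import normalize_aa
from .energy_balance import CollectionRecord, marker_digestibility

#: Basal endogenous phosphorus loss, mg per kg of DM intake.
DEFAULT_BASAL_P_LOSS_MG_PER_KG_DMI = 190.0


def _norm_key(key: str) -> str:
    """Amino-acid keys to canonical three-letter codes; others unchanged."""
    try:
        return normalize_aa(key)
    except KeyError:
        return key


@dataclass(frozen=True)
class DigestaRecord:
    """Ileal digesta of one pig-period, with marker and nutrient assays.

    Concentrations are g/kg DM in both the diet and the digesta; the
    titanium marker is % of DM in both.
    """

    pig_id: str
    diet: str
    ti_diet: float
    ti_digesta: float
    conc_diet: Mapping[str, float] = field(default_factory=dict)
    conc_digesta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.ti_diet <= 0 or self.ti_digesta <= 0:
            raise ValueError(f"{self.pig_id}: marker concentrations must be positive")
        object.__setattr__(
            self, "conc_diet", {_norm_key(k): v for k, v in dict(self.conc_diet).items()}
        )
        object.__setattr__(
            self, "conc_digesta",
            {_norm_key(k): v for k, v in dict(self.conc_digesta).items()},
        )
        for m in (self.conc_diet, self.conc_digesta):
            for k, v in m.items():
                if v < 0 or not math.isfinite(v):
                    raise ValueError(f"{self.pig_id}: {k} concentration {v}")


@dataclass(frozen=True)
class DigestibilityResult:
    """Mean apparent and standardized digestibility of one nutrient, %.

    ``sd`` is the between-pig standard deviation of the apparent
    coefficient; the standardized coefficient shares it because the
    endogenous correction is a per-diet constant.
    """

    nutrient: str
    apparent: float
    standardized: float
    basal_endogenous_loss: float  # g (P: mg) per kg DM intake
    n: int
    sd: Optional[float] = None

    def __post_init__(self):
        if self.standardized < self.apparent - 1e-9:
            raise ValueError(
                f"{self.nutrient}: standardized ({self.standardized}) below "
                f"apparent ({self.apparent}); endogenous correction is additive"
            )


def attd_p(rec: CollectionRecord, p_diet: float) -> float:
    """Apparent total tract digestibility of phosphorus, %, by marker ratio.

    ``p_diet`` and the record's fecal ``"P"`` entry are % of DM.
    """
    if rec.ti_diet is None or rec.ti_feces is None:
        raise ValueError(f"{rec.pig_id}: marker concentrations missing")
    if "P" not in rec.fecal_nutrients:
        raise ValueError(f"{rec.pig_id}: fecal P concentration missing")
    return 100.0 * marker_digestibility(
        p_diet, rec.fecal_nutrients["P"], rec.ti_diet, rec.ti_feces
    )


def sttd_from_attd(
    attd: float,
    nutrient_intake_per_kg_dmi: float,
    basal_loss: float = DEFAULT_BASAL_P_LOSS_MG_PER_KG_DMI,
) -> float:
    """Standardize a total-tract digestibility for basal endogenous loss.

    STTD (%) = ATTD + 100 x (basal_loss / 1000) / intake, with the
    nutrient intake in g per kg of DM intake and the basal loss in mg per
    kg of DM intake (the phosphorus convention).
    """
    if nutrient_intake_per_kg_dmi <= 0:
        raise ValueError("nutrient intake per kg DMI must be positive")
    if basal_loss < 0:
        raise ValueError("basal endogenous loss must be >= 0")
    return attd + 100.0 * (basal_loss / 1000.0) / nutrient_intake_per_kg_dmi


def endogenous_flow(rec: DigestaRecord, nutrient: str) -> float:
    """Ileal flow of a nutrient, g per kg DM intake, from one digesta record.

    flow = digesta concentration x (marker_diet / marker_digesta): the
    marker ratio converts per-kg-digesta-DM to per-kg-diet-DM.
    """
    if nutrient not in rec.conc_digesta:
        raise KeyError(f"{rec.pig_id}: no digesta concentration for {nutrient!r}")
    return rec.conc_digesta[nutrient] * rec.ti_diet / rec.ti_digesta


def basal_endogenous_aa(
    nfree_records: Sequence[DigestaRecord],
    nutrients: Optional[Iterable[str]] = None,
) -> dict[str, float]:
    """Basal endogenous amino-acid losses, g/kg DMI, from N-free-diet pigs.

    Averages the marker-corrected ileal flow over pigs for every nutrient
    assayed (or the explicit ``nutrients`` subset).
    """
    if not nfree_records:
        raise ValueError("no nitrogen-free-diet records supplied")
    if nutrients is None:
        keys = set(nfree_records[0].conc_digesta)
        for r in nfree_records[1:]:
            keys &= set(r.conc_digesta)
    else:
        keys = {_norm_key(n) for n in nutrients}
    return {
        n: statistics.fmean(endogenous_flow(r, n) for r in nfree_records)
        for n in sorted(keys)
    }


def digesta_records_to_df(records: Sequence[DigestaRecord]):
    """Tabulate digesta records; diet and digesta concentrations become
    ``diet_<nutrient>_gkg`` / ``digesta_<nutrient>_gkg`` columns."""
    import pandas as pd

    nutrients = sorted({n for r in records for n in r.conc_diet}
                       | {n for r in records for n in r.conc_digesta})
    rows = []
    for r in records:
        row = {"pig_id": r.pig_id, "diet": r.diet,
               "ti_diet_pct": r.ti_diet, "ti_digesta_pct": r.ti_digesta}
        for n in nutrients:
            row[f"diet_{n}_gkg"] = r.conc_diet.get(n)
            row[f"digesta_{n}_gkg"] = r.conc_digesta.get(n)
        rows.append(row)
    return pd.DataFrame(rows)


def read_digesta_records_csv(path) -> list[DigestaRecord]:
    """Read digesta records written by :func:`digesta_records_to_df`."""
    import pandas as pd

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    diet_cols = {c: c[len("diet_"):-len("_gkg")] for c in df.columns
                 if c.startswith("diet_") and c.endswith("_gkg")}
    dig_cols = {c: c[len("digesta_"):-len("_gkg")] for c in df.columns
                if c.startswith("digesta_") and c.endswith("_gkg")}
    records = []
    for _, row in df.iterrows():
        records.append(
            DigestaRecord(
                pig_id=str(row["pig_id"]),
                diet=str(row["diet"]),
                ti_diet=float(row["ti_diet_pct"]),
                ti_digesta=float(row["ti_digesta_pct"]),
                conc_diet={n: float(row[c]) for c, n in diet_cols.items()
                           if pd.notna(row[c])},
                conc_digesta={n: float(row[c]) for c, n in dig_cols.items()
                              if pd.notna(row[c])},
            )
        )
    return records


def aid_sid(
    test_records: Sequence[DigestaRecord],
    endogenous: Mapping[str, float],
    nutrients: Optional[Iterable[str]] = None,
) -> list[DigestibilityResult]:
    """Apparent and standardized ileal digestibility per nutrient, %.

    Per pig, AID = 100 x marker digestibility of the nutrient, and
    SID = AID + 100 x endogenous_flow / diet_concentration with both the
    flow (g/kg DMI) and the diet concentration (g/kg DM) on the marker's
    normalization.  A nutrient whose endogenous flow is not supplied
    raises rather than silently standardizing with zero.  Negative AID
    and SID above 100% pass through unclipped.
    """
    if not test_records:
        raise ValueError("no test-diet records supplied")
    if nutrients is None:
        keys = set(test_records[0].conc_diet)
        for r in test_records[1:]:
            keys &= set(r.conc_diet)
        keys = sorted(keys)
    else:
        keys = [_norm_key(n) for n in nutrients]
    results = []
    for n in keys:
        if n not in endogenous:
            raise KeyError(f"no endogenous loss supplied for {n!r}")
        aids, sids = [], []
        for r in test_records:
            diet_conc = r.conc_diet[n]
            aid = 100.0 * marker_digestibility(
                diet_conc, r.conc_digesta.get(n, 0.0), r.ti_diet, r.ti_digesta
            )
            aids.append(aid)
            sids.append(aid + 100.0 * endogenous[n] / diet_conc)
        results.append(
            DigestibilityResult(
                nutrient=n,
                apparent=statistics.fmean(aids),
                standardized=statistics.fmean(sids),
                basal_endogenous_loss=endogenous[n],
                n=len(aids),
                sd=statistics.stdev(aids) if len(aids) > 1 else None,
            )
        )
    return results
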
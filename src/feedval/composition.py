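"""Ingredient composition model and dry-matter basis algebra.

Feed tables report nutrient concentrations either per kilogram of feed
*as fed* (moisture included) or per kilogram of *dry matter* (DM).
Laboratory reports are typically as-fed while every energy prediction
equation operates on a DM basis, so an explicit, lossless conversion
between the two bases underpins everything downstream.

Concentrations are stored as percent of mass (matching how feed
composition tables are printed) and gross energy as kcal/kg.  A nutrient
that was not analyzed is ``None``, never silently zero: equations that
need it fail loudly instead of quietly shifting the answer.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd


class Basis(str, Enum):
    """Reporting basis of a composition: per kg as-fed or per kg DM."""

    AS_FED = "as_fed"
    DM = "dm"


class InvalidCompositionError(ValueError):
    """A composition violates a physical constraint (e.g. dm_frac = 0)."""


class MissingInputError(KeyError):
    """A required analyzed nutrient is absent from a composition."""

    def __init__(self, field_name: str, ingredient: str = ""):
        self.field_name = field_name
        self.ingredient = ingredient
        where = f" for {ingredient!r}" if ingredient else ""
        super().__init__(f"missing analyzed input {field_name!r}{where}")


#: Canonical three-letter amino-acid codes accepted by :func:`normalize_aa`.
AA_CODES = (
    "Arg", "His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Trp", "Val",
    "Ala", "Asp", "Cys", "Glu", "Gly", "Pro", "Ser", "Tyr",
)
_AA_LOOKUP = {c.lower(): c for c in AA_CODES}

#: Fields scaled by the DM fraction on a basis change.
_SCALED_FIELDS = ("ge", "cp", "ee", "ash", "ndf", "adf", "ca", "p")


def normalize_aa(code: str) -> str:
    """Normalize an amino-acid name to its three-letter code (case-insensitive)."""
    key = code.strip().lower()
    if key not in _AA_LOOKUP:
        raise KeyError(f"unknown amino acid code {code!r}")
    return _AA_LOOKUP[key]


@dataclass(frozen=True)
class IngredientComposition:
    """Analyzed composition of one ingredient (or mixed diet).

    Parameters
    ----------
    name : str
        Ingredient identifier.
    basis : Basis
        Whether concentrations and ``ge`` are per kg as-fed or per kg DM.
    dm_frac : float
        Dry-matter fraction in (0, 1].
    ge : float, optional
        Gross energy, kcal/kg on ``basis``.
    cp, ee, ash, ndf, adf, ca, p : float, optional
        Crude protein, ether extract (crude fat), ash, neutral/acid
        detergent fiber, calcium and phosphorus, % of mass on ``basis``.
        ``None`` marks "not analyzed".
    aa : mapping
        Amino-acid concentrations, % of mass, keyed by three-letter code.
    """

    name: str
    basis: Basis
    dm_frac: float
    ge: Optional[float] = None
    cp: Optional[float] = None
    ee: Optional[float] = None
    ash: Optional[float] = None
    ndf: Optional[float] = None
    adf: Optional[float] = None
    ca: Optional[float] = None
    p: Optional[float] = None
    aa: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.dm_frac <= 1.0):
            raise InvalidCompositionError(
                f"{self.name}: dm_frac must be in (0, 1], got {self.dm_frac}"
            )
        for fname in _SCALED_FIELDS:
            v = getattr(self, fname)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise InvalidCompositionError(
                    f"{self.name}: {fname} must be finite and >= 0, got {v}"
                )
        for fname in ("cp", "ee", "ash", "ndf", "adf", "ca", "p"):
            v = getattr(self, fname)
            if v is not None and v > 100.0 + 1e-9:
                raise InvalidCompositionError(
                    f"{self.name}: {fname} = {v}% exceeds 100% of mass"
                )
        object.__setattr__(
            self, "aa", {normalize_aa(k): float(v) for k, v in dict(self.aa).items()}
        )
        for code, v in self.aa.items():
            if not math.isfinite(v) or v < 0:
                raise InvalidCompositionError(f"{self.name}: aa {code} = {v}")

    def require(self, field_name: str) -> float:
        """Return an analyzed value or raise :class:`MissingInputError`."""
        v = getattr(self, field_name)
        if v is None:
            raise MissingInputError(field_name, self.name)
        return v


def convert_basis(comp: IngredientComposition, target: Basis) -> IngredientComposition:
    """Re-express a composition on the ``target`` basis.

    As-fed -> DM divides every concentration and GE by the DM fraction;
    DM -> as-fed multiplies.  The operation is an exact linear scaling:
    converting back returns the original values (round-trip identity) and
    converting to the current basis is the identity.
    """
    target = Basis(target)
    if comp.basis == target:
        return comp
    if comp.dm_frac <= 0:
        raise InvalidCompositionError(f"{comp.name}: dm_frac must be positive")
    factor = 1.0 / comp.dm_frac if target == Basis.DM else comp.dm_frac
    changes = {
        fname: (None if getattr(comp, fname) is None else getattr(comp, fname) * factor)
        for fname in _SCALED_FIELDS
    }
    changes["aa"] = {k: v * factor for k, v in comp.aa.items()}
    changes["basis"] = target
    return dataclasses.replace(comp, **changes)


# Coefficients of the composition-based gross-energy estimate
# (kcal/kg DM; EE, CP and ash as % of DM).
_GE_INTERCEPT = 4143.0
_GE_EE, _GE_CP, _GE_ASH = 56.0, 15.0, -44.0


def calculated_ge(comp: IngredientComposition) -> float:
    """Estimate gross energy (kcal/kg DM) from proximate composition.

    GE = 4,143 + 56 x %EE + 15 x %CP - 44 x %ash, with all inputs on a
    % DM basis.  Used by the prediction-equation variants that do not
    take the bomb-calorimeter GE as input.
    """
    dm = convert_basis(comp, Basis.DM)
    return (
        _GE_INTERCEPT
        + _GE_EE * dm.require("ee")
        + _GE_CP * dm.require("cp")
        + _GE_ASH * dm.require("ash")
    )


@dataclass(frozen=True)
class DietSpec:
    """A formulated diet: ingredient inclusion plus analyzed composition.

    ``ingredients`` maps ingredient name to inclusion fraction (must sum
    to 1), ``analyzed`` holds the mixed diet's own analyzed composition,
    and ``marker_conc`` is the analyzed titanium concentration (% as-fed)
    of the indigestible marker mixed into the diet.
    """

    name: str
    ingredients: Mapping[str, float]
    analyzed: Optional[IngredientComposition] = None
    marker_conc: Optional[float] = None

    def __post_init__(self):
        total = sum(self.ingredients.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidCompositionError(
                f"diet {self.name}: inclusion fractions sum to {total}, expected 1"
            )
        if self.marker_conc is not None and self.marker_conc <= 0:
            raise InvalidCompositionError(
                f"diet {self.name}: marker concentration must be > 0"
            )


# ---------------------------------------------------------------------------
# CSV interchange

_CSV_COLUMNS = [
    "name", "basis", "dm_pct", "ge_kcal_kg", "cp_pct", "ee_pct",
    "ash_pct", "ndf_pct", "adf_pct", "ca_pct", "p_pct",
]
_FIELD_FOR_COLUMN = {
    "ge_kcal_kg": "ge", "cp_pct": "cp", "ee_pct": "ee", "ash_pct": "ash",
    "ndf_pct": "ndf", "adf_pct": "adf", "ca_pct": "ca", "p_pct": "p",
}


def read_composition_csv(path) -> list[IngredientComposition]:
    """Read an ingredient composition table (one row per ingredient).

    Expected columns: ``name, basis, dm_pct, ge_kcal_kg, cp_pct, ee_pct,
    ash_pct, ndf_pct, adf_pct, ca_pct, p_pct`` plus any number of
    ``aa_<code>_pct`` columns.  Empty cells become ``None``.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("name", "basis", "dm_pct") if c not in df.columns]
    if missing:
        raise InvalidCompositionError(f"composition CSV lacks columns {missing}")
    aa_cols = {
        c: normalize_aa(c[3:-4])
        for c in df.columns
        if c.startswith("aa_") and c.endswith("_pct")
    }
    out = []
    for _, row in df.iterrows():
        kwargs = {
            "name": str(row["name"]),
            "basis": Basis(str(row["basis"])),
            "dm_frac": float(row["dm_pct"]) / 100.0,
        }
        for col, fname in _FIELD_FOR_COLUMN.items():
            if col in df.columns and pd.notna(row[col]):
                kwargs[fname] = float(row[col])
        kwargs["aa"] = {
            code: float(row[col]) for col, code in aa_cols.items() if pd.notna(row[col])
        }
        out.append(IngredientComposition(**kwargs))
    return out


def write_composition_csv(comps: Sequence[IngredientComposition], path) -> None:
    """Write compositions with the same column schema ``read_composition_csv`` reads."""
    aa_codes = sorted({code for c in comps for code in c.aa})
    rows = []
    for c in comps:
        row = {"name": c.name, "basis": c.basis.value, "dm_pct": c.dm_frac * 100.0}
        for col, fname in _FIELD_FOR_COLUMN.items():
            row[col] = getattr(c, fname)
        for code in aa_codes:
            row[f"aa_{code.lower()}_pct"] = c.aa.get(code)
        rows.append(row)
    cols = _CSV_COLUMNS + [f"aa_{code.lower()}_pct" for code in aa_codes]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_diet_yaml(path) -> dict[str, dict[str, DietSpec]]:
    """Read diet specifications grouped by experiment from YAML.

    Each diet entry holds an ``ingredients`` map (percent of diet, summing
    to 100), an optional ``analyzed`` block (same keys as the composition
    CSV columns, plus ``aa_pct``), and an optional ``ti_pct`` analyzed
    marker concentration (% as-fed).
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, dict[str, DietSpec]] = {}
    for experiment, diets in raw.items():
        out[experiment] = {}
        for name, entry in diets.items():
            analyzed = None
            if "analyzed" in entry:
                a = entry["analyzed"]
                analyzed = IngredientComposition(
                    name=f"{experiment}:{name}",
                    basis=Basis.AS_FED,
                    dm_frac=a["dm_pct"] / 100.0,
                    ge=a.get("ge_kcal_kg"),
                    cp=a.get("cp_pct"),
                    ee=a.get("ee_pct"),
                    ash=a.get("ash_pct"),
                    ndf=a.get("ndf_pct"),
                    adf=a.get("adf_pct"),
                    ca=a.get("ca_pct"),
                    p=a.get("p_pct"),
                    aa=entry.get("aa_pct", {}),
                )
            out[experiment][name] = DietSpec(
                name=name,
                ingredients={k: v / 100.0 for k, v in entry["ingredients"].items()},
                analyzed=analyzed,
                marker_conc=entry.get("ti_pct"),
            )
    return out


def load_reference_diets() -> dict[str, dict[str, DietSpec]]:
    """Packaged diet formulations of the three trials (energy balance,
    phosphorus digestibility, ileal amino-acid digestibility)."""
    return read_diet_yaml(Path(__file__).parent / "data" / "diets.yaml")


def load_reference_ingredients() -> dict[str, IngredientComposition]:
    """Packaged as-fed composition table of the three dehydrated food waste
    sources (fish waste FW, supermarket waste SMW, fruit & vegetable waste
    FVW) and the corn used as the basal-diet energy source."""
    path = Path(__file__).parent / "data" / "ingredients.csv"
    return {c.name: c for c in read_composition_csv(path)}
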
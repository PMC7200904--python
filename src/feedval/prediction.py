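"""Registry of published DE/ME prediction equations for swine feeds.

Three equation families are implemented, each with its own input
convention (the single most common source of transcription error when
these equations are applied):

* ``NOBLET_PEREZ`` (ids 1-7): chemical-composition equations with
  nutrients in g/kg DM and GE in kcal/kg DM.  Equations 1 and 5 take the
  bomb-calorimeter (analyzed) GE; 2 and 6 the composition-estimated GE;
  5-7 are the matching ME forms, DE minus 0.68 x CP (g/kg DM).
* ``KERR`` (ids 8-15): stepwise regressions with nutrients in % DM and
  GE in kcal/kg DM.  These can go negative on low-protein, low-fat
  feeds; the value is returned as-is and flagged in the outcome notes.
* ``NOBLET_JAGUELIN`` (ids 16-19): regressions on in vitro organic-matter
  digestibility (OMdv, g/kg DM) plus chemical inputs in g/kg DM,
  evaluated in MJ/kg DM and converted to kcal/kg DM (1 MJ = 238.834
  kcal).  OMdv (and crude fiber, for id 18) are caller-supplied since no
  proximate assay provides them.

Every equation is affine in its inputs.  A composition lacking a
required analyzed nutrient raises :class:`~feedval.composition.MissingInputError`
naming the field — an unanalyzed NDF is never silently zero.  For feeds
whose NDF assay is considered unreliable (animal products), an explicit
``zero_ndf`` override evaluates the fiber term at zero and records that
choice in the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .composition import (
    Basis,
    IngredientComposition,
    MissingInputError,
    calculated_ge,
    convert_basis,
)

#: Conversion factor between megajoules and kilocalories.
KCAL_PER_MJ = 238.834


def mj_to_kcal(x: float) -> float:
    """Convert an energy value from MJ to kcal (1 MJ = 238.834 kcal)."""
    return x * KCAL_PER_MJ


class Family(str, Enum):
    NOBLET_PEREZ = "noblet_perez"
    KERR = "kerr"
    NOBLET_JAGUELIN = "noblet_jaguelin"


@dataclass(frozen=True)
class EquationSpec:
    """One published prediction equation and its input contract."""

    id: str
    family: Family
    output: str                       # "DE" or "ME"
    required: tuple[str, ...]         # composition/assay fields needed
    description: str
    func: Callable[[dict], float] = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class PredictionOutcome:
    """A single (equation, ingredient) prediction, kcal/kg DM."""

    equation_id: str
    ingredient: str
    predicted: float
    output: str
    inputs_used: Mapping[str, float] = field(default_factory=dict)
    notes: str = ""


def _np1(v):  # analyzed-GE chemical equation
    return 1161.0 + 0.749 * v["ge"] - 4.3 * v["ash_gkg"] - 4.1 * v["ndf_gkg"]


def _np2(v):  # calculated-GE variant
    return 1161.0 + 0.749 * v["ge_calc"] - 4.3 * v["ash_gkg"] - 4.1 * v["ndf_gkg"]


def _np3(v):  # proximate-only DE
    return (4168.0 - 9.1 * v["ash_gkg"] + 1.9 * v["cp_gkg"]
            + 3.9 * v["ee_gkg"] - 3.6 * v["ndf_gkg"])


def _np4(v):  # proximate-only ME
    return (4194.0 - 9.2 * v["ash_gkg"] + 1.0 * v["cp_gkg"]
            + 4.1 * v["ee_gkg"] - 3.5 * v["ndf_gkg"])


_EQ_DEFS: list[tuple[str, Family, str, tuple[str, ...], str, Callable[[dict], float]]] = [
    ("1", Family.NOBLET_PEREZ, "DE", ("ge", "ash", "ndf"),
     "DE = 1,161 + 0.749 GE - 4.3 ash - 4.1 NDF (g/kg DM)", _np1),
    ("2", Family.NOBLET_PEREZ, "DE", ("cp", "ee", "ash", "ndf"),
     "DE = 1,161 + 0.749 calcGE - 4.3 ash - 4.1 NDF (g/kg DM)", _np2),
    ("3", Family.NOBLET_PEREZ, "DE", ("cp", "ee", "ash", "ndf"),
     "DE = 4,168 - 9.1 ash + 1.9 CP + 3.9 EE - 3.6 NDF (g/kg DM)", _np3),
    ("4", Family.NOBLET_PEREZ, "ME", ("cp", "ee", "ash", "ndf"),
     "ME = 4,194 - 9.2 ash + 1.0 CP + 4.1 EE - 3.5 NDF (g/kg DM)", _np4),
    ("5", Family.NOBLET_PEREZ, "ME", ("ge", "ash", "ndf", "cp"),
     "ME = DE[1] - 0.68 CP (g/kg DM)",
     lambda v: _np1(v) - 0.68 * v["cp_gkg"]),
    ("6", Family.NOBLET_PEREZ, "ME", ("cp", "ee", "ash", "ndf"),
     "ME = DE[2] - 0.68 CP (g/kg DM)",
     lambda v: _np2(v) - 0.68 * v["cp_gkg"]),
    ("7", Family.NOBLET_PEREZ, "ME", ("cp", "ee", "ash", "ndf"),
     "ME = DE[3] - 0.68 CP (g/kg DM)",
     lambda v: _np3(v) - 0.68 * v["cp_gkg"]),
    ("8", Family.KERR, "DE", ("ge",),
     "DE = 1.26 GE - 2,468 (GE kcal/kg DM)",
     lambda v: 1.26 * v["ge"] - 2468.0),
    ("9", Family.KERR, "DE", ("cp", "ee", "ash"),
     "DE = 56.1 CP + 73.4 EE - 12.5 ash - 669 (% DM)",
     lambda v: 56.1 * v["cp_pct"] + 73.4 * v["ee_pct"] - 12.5 * v["ash_pct"] - 669.0),
    ("10", Family.KERR, "DE", ("ash",),
     "DE = -87.5 ash + 5,420 (% DM)",
     lambda v: -87.5 * v["ash_pct"] + 5420.0),
    ("11", Family.KERR, "DE", ("cp", "ee", "ash"),
     "DE = 46.7 CP + 59.2 EE - 36.5 ash + 665 (% DM)",
     lambda v: 46.7 * v["cp_pct"] + 59.2 * v["ee_pct"] - 36.5 * v["ash_pct"] + 665.0),
    ("12", Family.KERR, "ME", ("ge",),
     "ME = 1.15 GE - 2,331 (GE kcal/kg DM)",
     lambda v: 1.15 * v["ge"] - 2331.0),
    ("13", Family.KERR, "ME", ("cp", "ee", "ash"),
     "ME = 48.1 CP + 75.9 EE - 18.0 ash - 443 (% DM)",
     lambda v: 48.1 * v["cp_pct"] + 75.9 * v["ee_pct"] - 18.0 * v["ash_pct"] - 443.0),
    ("14", Family.KERR, "ME", ("ash",),
     "ME = -84.0 ash + 4,996 (% DM)",
     lambda v: -84.0 * v["ash_pct"] + 4996.0),
    ("15", Family.KERR, "ME", ("cp", "ee", "ash"),
     "ME = 36.8 CP + 49.7 EE - 43.1 ash + 1,192 (% DM)",
     lambda v: 36.8 * v["cp_pct"] + 49.7 * v["ee_pct"] - 43.1 * v["ash_pct"] + 1192.0),
    ("16", Family.NOBLET_JAGUELIN, "DE", ("omdv",),
     "DE (MJ) = 0.0189 OMdv (g/kg DM)",
     lambda v: mj_to_kcal(0.0189 * v["omdv_gkg"])),
    ("17", Family.NOBLET_JAGUELIN, "DE", ("omdv", "ee"),
     "DE (MJ) = 1.12 + 0.0168 OMdv + 0.0184 EE (g/kg DM)",
     lambda v: mj_to_kcal(1.12 + 0.0168 * v["omdv_gkg"] + 0.0184 * v["ee_gkg"])),
    ("18", Family.NOBLET_JAGUELIN, "DE", ("omdv", "ee", "cf"),
     "DE (MJ) = 5.02 + 0.0127 OMdv + 0.0172 EE - 0.0124 CF (g/kg DM)",
     lambda v: mj_to_kcal(5.02 + 0.0127 * v["omdv_gkg"] + 0.0172 * v["ee_gkg"]
                          - 0.0124 * v["cf_gkg"])),
    ("19", Family.NOBLET_JAGUELIN, "DE", ("omdv", "ee", "adf"),
     "DE (MJ) = 6.05 + 0.0116 OMdv + 0.0166 EE - 0.0135 ADF (g/kg DM)",
     lambda v: mj_to_kcal(6.05 + 0.0116 * v["omdv_gkg"] + 0.0166 * v["ee_gkg"]
                          - 0.0135 * v["adf_gkg"])),
]

#: All registered equations, keyed by id ("1" .. "19").
EQUATIONS: dict[str, EquationSpec] = {
    eid: EquationSpec(eid, fam, out, req, desc, fn)
    for eid, fam, out, req, desc, fn in _EQ_DEFS
}

DE_EQUATION_IDS = tuple(e.id for e in EQUATIONS.values() if e.output == "DE")
ME_EQUATION_IDS = tuple(e.id for e in EQUATIONS.values() if e.output == "ME")


def _inputs(
    comp: IngredientComposition,
    required: Iterable[str],
    omdv: Optional[float],
    crude_fiber: Optional[float],
    zero_ndf: bool,
) -> dict:
    """Assemble the per-family input namespace on a DM basis."""
    dm = convert_basis(comp, Basis.DM)
    v: dict = {}
    for fname in required:
        if fname == "omdv":
            if omdv is None:
                raise MissingInputError("omdv", comp.name)
            v["omdv_gkg"] = float(omdv)
        elif fname == "cf":
            if crude_fiber is None:
                raise MissingInputError("cf", comp.name)
            v["cf_gkg"] = float(crude_fiber) * 10.0
        elif fname == "ndf" and zero_ndf:
            v["ndf_gkg"] = 0.0
        elif fname == "ge":
            v["ge"] = dm.require("ge")
        else:
            pct = dm.require(fname)
            v[f"{fname}_pct"] = pct
            v[f"{fname}_gkg"] = pct * 10.0
    if "ge_calc" not in v and {"cp", "ee", "ash"} <= set(required):
        v["ge_calc"] = calculated_ge(dm)
    return v


def predict(
    eq: "EquationSpec | str",
    comp: IngredientComposition,
    omdv: Optional[float] = None,
    crude_fiber: Optional[float] = None,
    zero_ndf: bool = False,
) -> PredictionOutcome:
    """Evaluate one prediction equation on one composition.

    Parameters
    ----------
    eq : EquationSpec or str
        Registered equation or its id.
    comp : IngredientComposition
        On either basis; converted to DM internally.
    omdv : float, optional
        In vitro OM digestibility, g/kg DM (required by ids 16-19).
    crude_fiber : float, optional
        Crude fiber, % DM (required by id 18).
    zero_ndf : bool
        Evaluate the NDF term at zero regardless of the analyzed value
        (the animal-product override); noted in the outcome.
    """
    if isinstance(eq, str):
        if eq not in EQUATIONS:
            raise KeyError(f"unknown equation id {eq!r}")
        eq = EQUATIONS[eq]
    v = _inputs(comp, eq.required, omdv, crude_fiber, zero_ndf)
    predicted = eq.func(v)
    notes = []
    if zero_ndf and "ndf" in eq.required:
        notes.append("NDF term evaluated at 0 (override)")
    if predicted < 0:
        notes.append("negative prediction (equation outside its calibration range)")
    return PredictionOutcome(
        equation_id=eq.id,
        ingredient=comp.name,
        predicted=predicted,
        output=eq.output,
        inputs_used=v,
        notes="; ".join(notes),
    )


def predict_all(
    comps: Sequence[IngredientComposition],
    eq_ids: Optional[Sequence[str]] = None,
    omdv: Optional[Mapping[str, float]] = None,
    crude_fiber: Optional[Mapping[str, float]] = None,
    zero_ndf_for: Iterable[str] = (),
) -> pd.DataFrame:
    """Batch-evaluate equations over ingredients.

    Returns one row per (ingredient, equation) with columns ``ingredient,
    equation, output, predicted, notes``; a pair whose required input is
    missing is reported with a NaN prediction and an explanatory note
    rather than dropped.
    """
    if eq_ids is None:
        eq_ids = list(EQUATIONS)
    zero_ndf_for = set(zero_ndf_for)
    rows = []
    for comp in comps:
        for eid in eq_ids:
            if eid not in EQUATIONS:
                raise KeyError(f"unknown equation id {eid!r}")
            try:
                out = predict(
                    EQUATIONS[eid],
                    comp,
                    omdv=None if omdv is None else omdv.get(comp.name),
                    crude_fiber=None if crude_fiber is None else crude_fiber.get(comp.name),
                    zero_ndf=comp.name in zero_ndf_for,
                )
                rows.append(
                    {"ingredient": comp.name, "equation": eid, "output": out.output,
                     "predicted": out.predicted, "notes": out.notes}
                )
            except MissingInputError as err:
                rows.append(
                    {"ingredient": comp.name, "equation": eid,
                     "output": EQUATIONS[eid].output, "predicted": float("nan"),
                     "notes": f"not evaluated: {err.field_name} missing"}
                )
    return pd.DataFrame(rows, columns=["ingredient", "equation", "output", "predicted", "notes"])
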
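"""Synthetic digestibility-trial generator with known ground truth.

In vivo digestibility means cannot be recomputed at a desk — they live
in pigs.  What *can* be verified is the estimation calculus: every
estimator in this package, applied to data generated by exact marker and
energy mass balance around known true digestibilities, must return those
truths exactly; under realistic assay noise it must recover them without
bias.  This module builds such datasets.

The default scenario mirrors the three-trial design the package is
built around: a corn-based energy-balance trial (a 96.9%-corn basal diet
and three test diets with 30% food waste replacing corn), a
cornstarch-sucrose phosphorus trial, and an ileal amino-acid trial with
a nitrogen-free diet, each with 9 pigs per diet of 16.37 +/- 1.9 kg fed
three times maintenance.  Its true digestibility values are the
published in vivo means of the three food waste sources, so recovery
tests exercise the same numerical regime as the real data, including
FVW's negative apparent amino-acid digestibilities.

Noise is multiplicative lognormal on assayed concentrations (assays are
positive and CV-scaled), with independent, documented substreams per
record type so adding one trial never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .composition import Basis, convert_basis, load_reference_diets
from .digestibility import DigestaRecord
from .energy_balance import CollectionRecord, EnergyValues, diet_energy, feed_allowance, ingredient_energy_by_difference

# Substream labels: (seed, _STREAM_x) seeds one independent generator each.
_STREAM_ENERGY, _STREAM_P, _STREAM_ILEAL = 1, 2, 3


@dataclass(frozen=True)
class NoiseSpec:
    """Assay noise, as coefficients of variation (0 = noise-free)."""

    marker_cv: float = 0.05   # titanium assay, feces/digesta
    ge_cv: float = 0.05       # bomb calorimetry, feces/urine
    conc_cv: float = 0.05     # nutrient assays (P, amino acids)

    def __post_init__(self):
        for f in ("marker_cv", "ge_cv", "conc_cv"):
            v = getattr(self, f)
            if v < 0 or v > 1:
                raise ValueError(f"{f} = {v} outside [0, 1]")


NO_NOISE = NoiseSpec(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class EnergyDietTruth:
    """Ground truth for one diet of a total-collection trial (DM basis)."""

    name: str
    ge: float                 # kcal/kg DM
    dm_frac: float
    ti_pct_dm: float          # marker, % of diet DM
    de: float                 # kcal/kg DM
    me: float                 # kcal/kg DM
    dm_digestibility: float = 0.85    # fraction; sets fecal bulk only
    p_pct_dm: Optional[float] = None  # analyzed diet P, % DM
    attd_p: Optional[float] = None    # true ATTD of P, %

    def __post_init__(self):
        if not (0.0 < self.de <= self.ge):
            raise ValueError(f"{self.name}: DE must be in (0, GE]")
        if not (0.0 < self.me <= self.de):
            raise ValueError(f"{self.name}: ME must be in (0, DE]")
        if not (0.0 < self.dm_digestibility < 1.0):
            raise ValueError(f"{self.name}: dm_digestibility outside (0, 1)")
        if self.attd_p is not None and not (-100.0 <= self.attd_p <= 110.0):
            raise ValueError(f"{self.name}: ATTD P {self.attd_p}% implausible")


@dataclass(frozen=True)
class IlealDietTruth:
    """Ground truth for one diet of the ileal amino-acid trial.

    ``aid`` maps nutrient -> true apparent ileal digestibility (%); a
    ``None`` aid marks the nitrogen-free diet, whose ileal nutrient flows
    are the basal endogenous losses alone.  Apparent coefficients far
    below -100% are legitimate here: endogenous secretion on a
    low-protein fibrous diet can exceed the dietary supply severalfold.
    """

    name: str
    ti_pct_dm: float
    aa_diet_gkg: Mapping[str, float] = field(default_factory=dict)  # g/kg DM
    aid: Optional[Mapping[str, float]] = None
    ileal_dm_digestibility: float = 0.80

    def __post_init__(self):
        if self.ti_pct_dm <= 0:
            raise ValueError(f"{self.name}: marker concentration must be positive")
        if not (0.0 < self.ileal_dm_digestibility < 1.0):
            raise ValueError(f"{self.name}: ileal DM digestibility outside (0, 1)")
        if self.aid is not None:
            for k, v in self.aid.items():
                if not (-500.0 <= v <= 150.0):
                    raise ValueError(f"{self.name}: AID {k} = {v}% implausible")


@dataclass(frozen=True)
class TrialScenario:
    """Complete specification of the synthetic three-trial study."""

    energy_diets: tuple[EnergyDietTruth, ...] = ()
    p_diets: tuple[EnergyDietTruth, ...] = ()
    ileal_diets: tuple[IlealDietTruth, ...] = ()
    endogenous_aa: Mapping[str, float] = field(default_factory=dict)  # g/kg DMI
    ingredient_truth: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    basal_frac_in_test: float = 0.669
    basal_frac_in_basal: float = 0.969
    test_frac: float = 0.30
    n_pigs_per_diet: int = 9
    bw_mean: float = 16.37    # kg
    bw_sd: float = 1.9        # kg
    urine_volume_l: float = 2.0
    noise: NoiseSpec = NoiseSpec()
    seed: int = 0

    def __post_init__(self):
        if self.n_pigs_per_diet < 1:
            raise ValueError("need at least one pig per diet")
        if self.bw_mean <= 0 or self.bw_sd < 0:
            raise ValueError("implausible body-weight parameters")
        for v in self.endogenous_aa.values():
            if v < 0:
                raise ValueError("endogenous flows must be >= 0")

    def sid_truth(self, diet: IlealDietTruth) -> dict[str, float]:
        """True SID implied by the diet's AID truth and the endogenous flows."""
        if diet.aid is None:
            raise ValueError(f"{diet.name} is the nitrogen-free diet")
        return {
            n: diet.aid[n] + 100.0 * self.endogenous_aa[n] / diet.aa_diet_gkg[n]
            for n in diet.aid
        }


def _lognorm_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise; exactly 1 when cv = 0.

    The normal deviates are always drawn so that the generated trial
    structure (body weights, intakes) is identical across noise settings
    for a given seed.
    """
    z = rng.standard_normal(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(z * sigma - 0.5 * sigma * sigma)


def _simulate_collection(
    sc: TrialScenario, diets: Sequence[EnergyDietTruth], stream: int
) -> list[CollectionRecord]:
    rng = np.random.default_rng([sc.seed, stream])
    records = []
    for diet in diets:
        n = sc.n_pigs_per_diet
        bw = np.maximum(1.0, rng.normal(sc.bw_mean, sc.bw_sd, n))
        f_ti = _lognorm_factors(rng, sc.noise.marker_cv, n)
        f_fge = _lognorm_factors(rng, sc.noise.ge_cv, n)
        f_uge = _lognorm_factors(rng, sc.noise.ge_cv, n)
        f_p = _lognorm_factors(rng, sc.noise.conc_cv, n)
        for i in range(n):
            allowance = feed_allowance(bw[i])               # kcal ME/day
            feed_intake = allowance / (diet.me * diet.dm_frac)
            dmi = feed_intake * diet.dm_frac
            fecal_output = dmi * (1.0 - diet.dm_digestibility)
            fecal_ge_total = dmi * (diet.ge - diet.de)      # kcal/day
            fecal_ge = fecal_ge_total / fecal_output        # kcal/kg fecal DM
            ti_feces = diet.ti_pct_dm * dmi / fecal_output  # marker mass balance
            urine_ge_total = dmi * (diet.de - diet.me)
            urine_ge = urine_ge_total / sc.urine_volume_l
            fecal_nutrients = {}
            if diet.p_pct_dm is not None and diet.attd_p is not None:
                fecal_nutrients["P"] = (
                    diet.p_pct_dm * (1.0 - diet.attd_p / 100.0) * dmi / fecal_output
                ) * f_p[i]
            records.append(
                CollectionRecord(
                    pig_id=f"{diet.name}-{i + 1:02d}",
                    diet=diet.name,
                    feed_intake=feed_intake,
                    diet_dm_frac=diet.dm_frac,
                    fecal_output=fecal_output,
                    fecal_ge=fecal_ge * f_fge[i],
                    urine_volume=sc.urine_volume_l,
                    urine_ge=urine_ge * f_uge[i],
                    ti_diet=diet.ti_pct_dm,
                    ti_feces=ti_feces * f_ti[i],
                    fecal_nutrients=fecal_nutrients,
                    bw=float(bw[i]),
                )
            )
    return records


def simulate_energy_trial(sc: TrialScenario) -> list[CollectionRecord]:
    """Generate the energy-balance trial's collection records.

    Feed intake follows the allowance rule on simulated body weights;
    fecal and urinary energy and the fecal marker concentration are set
    by exact mass balance from the diet truths, then perturbed by the
    scenario's multiplicative CVs.  With all CVs zero, every estimator
    recovers the truth exactly.
    """
    if not sc.energy_diets:
        raise ValueError("scenario has no energy-balance diets")
    return _simulate_collection(sc, sc.energy_diets, _STREAM_ENERGY)


def simulate_p_trial(sc: TrialScenario) -> list[CollectionRecord]:
    """Generate the phosphorus trial's collection records (fecal P assayed)."""
    if not sc.p_diets:
        raise ValueError("scenario has no phosphorus-trial diets")
    return _simulate_collection(sc, sc.p_diets, _STREAM_P)


def simulate_ileal_trial(sc: TrialScenario) -> list[DigestaRecord]:
    """Generate ileal digesta records, including the nitrogen-free diet.

    Digesta nutrient concentrations are solved from the true apparent
    digestibility (or, on the N-free diet, the endogenous flows) and the
    marker dilution implied by the true ileal DM digestibility.
    """
    if not sc.ileal_diets:
        raise ValueError("scenario has no ileal-trial diets")
    rng = np.random.default_rng([sc.seed, _STREAM_ILEAL])
    records = []
    for diet in sc.ileal_diets:
        digesta_dm_per_kg_dmi = 1.0 - diet.ileal_dm_digestibility
        ti_digesta = diet.ti_pct_dm / digesta_dm_per_kg_dmi
        nutrients = sorted(sc.endogenous_aa if diet.aid is None else diet.aid)
        for i in range(sc.n_pigs_per_diet):
            f_ti = _lognorm_factors(rng, sc.noise.marker_cv, 1)[0]
            f_conc = _lognorm_factors(rng, sc.noise.conc_cv, len(nutrients))
            conc_digesta = {}
            for j, n in enumerate(nutrients):
                if diet.aid is None:
                    flow = sc.endogenous_aa[n]  # g/kg DMI
                else:
                    flow = diet.aa_diet_gkg[n] * (1.0 - diet.aid[n] / 100.0)
                conc_digesta[n] = flow / digesta_dm_per_kg_dmi * f_conc[j]
            records.append(
                DigestaRecord(
                    pig_id=f"{diet.name}-{i + 1:02d}",
                    diet=diet.name,
                    ti_diet=diet.ti_pct_dm,
                    ti_digesta=ti_digesta * f_ti,
                    conc_diet=dict(diet.aa_diet_gkg),
                    conc_digesta=conc_digesta,
                )
            )
    return records


def recover_diet_energy(
    records: Sequence[CollectionRecord],
    diet_ge: Mapping[str, float],
    method: str = "marker",
) -> dict[str, EnergyValues]:
    """Per-diet mean DE/ME from collection records (pig-first averaging)."""
    by_diet: dict[str, list[EnergyValues]] = {}
    for rec in records:
        by_diet.setdefault(rec.diet, []).append(
            diet_energy(rec, diet_ge[rec.diet], method=method)
        )
    return {
        name: EnergyValues(
            de=float(np.mean([e.de for e in vals])),
            me=float(np.mean([e.me for e in vals])),
            ge=diet_ge[name],
        )
        for name, vals in by_diet.items()
    }


def recover_ingredient_energy(
    sc: TrialScenario,
    records: Sequence[CollectionRecord],
    basal_diet: str = "control",
    method: str = "marker",
) -> dict[str, EnergyValues]:
    """Difference-method ingredient DE/ME from an energy-trial dataset."""
    diet_ge = {d.name: d.ge for d in sc.energy_diets}
    diets = recover_diet_energy(records, diet_ge, method=method)
    basal = diets[basal_diet]
    return {
        name: ingredient_energy_by_difference(
            diets[name], basal,
            sc.basal_frac_in_test, sc.basal_frac_in_basal, sc.test_frac,
        )
        for name in diets
        if name != basal_diet
    }


def recover_p_attd(
    sc: TrialScenario, records: Optional[Sequence[CollectionRecord]] = None
) -> dict[str, float]:
    """Per-diet mean ATTD of phosphorus (%) from a phosphorus-trial dataset."""
    from .digestibility import attd_p

    if records is None:
        records = simulate_p_trial(sc)
    out = {}
    for diet in sc.p_diets:
        vals = [attd_p(r, diet.p_pct_dm) for r in records if r.diet == diet.name]
        out[diet.name] = float(np.mean(vals))
    return out


# ---------------------------------------------------------------------------
# Default scenario: the three-trial food waste study design.

#: In vivo ingredient energy values used as simulation ground truth
#: (kcal/kg DM): corn and the three dehydrated food waste sources.
INGREDIENT_ENERGY_TRUTH = {
    "corn": {"de": 3928.0, "me": 3875.0},
    "FW": {"de": 5057.0, "me": 4820.0},
    "SMW": {"de": 5071.0, "me": 4922.0},
    "FVW": {"de": 2570.0, "me": 2460.0},
}

#: True ATTD of phosphorus (%) per test ingredient.
ATTD_P_TRUTH = {"FW": 56.00, "SMW": 67.97, "FVW": 52.95}

#: True apparent ileal digestibility (%) per ingredient diet; CP plus the
#: ten indispensable and eight dispensable amino acids.
AID_TRUTH = {
    "FW": {"CP": 83.1, "Arg": 92.0, "His": 89.5, "Ile": 87.1, "Leu": 88.2,
           "Lys": 89.7, "Met": 92.4, "Phe": 87.7, "Thr": 83.4, "Trp": 91.2,
           "Val": 83.2, "Ala": 88.2, "Asp": 83.8, "Cys": 65.8, "Glu": 88.3,
           "Gly": 89.1, "Pro": 75.1, "Ser": 83.4, "Tyr": 86.1},
    "SMW": {"CP": 63.5, "Arg": 75.3, "His": 76.3, "Ile": 78.4, "Leu": 80.6,
            "Lys": 77.9, "Met": 82.9, "Phe": 78.1, "Thr": 68.2, "Trp": 83.2,
            "Val": 71.2, "Ala": 71.6, "Asp": 71.1, "Cys": 53.6, "Glu": 81.7,
            "Gly": 45.3, "Pro": -28.9, "Ser": 68.4, "Tyr": 73.9},
    "FVW": {"CP": -44.5, "Arg": -53.1, "His": -64.0, "Ile": -34.1, "Leu": -14.7,
            "Lys": -35.5, "Met": -7.4, "Phe": -9.8, "Thr": -64.2, "Trp": 15.0,
            "Val": -49.8, "Ala": -44.3, "Asp": -5.6, "Cys": -87.4, "Glu": 5.7,
            "Gly": -226.0, "Pro": -413.1, "Ser": -39.8, "Tyr": -91.1},
}

#: Standardized ileal digestibility (%) of the fish waste diet, used with
#: its AID to back out the basal endogenous flows of the default scenario.
_SID_TRUTH_FW = {
    "CP": 95.1, "Arg": 99.9, "His": 95.2, "Ile": 94.0, "Leu": 94.8,
    "Lys": 94.7, "Met": 95.0, "Phe": 94.4, "Thr": 93.3, "Trp": 99.2,
    "Val": 92.8, "Ala": 95.1, "Asp": 90.8, "Cys": 85.9, "Glu": 94.3,
    "Gly": 102.9, "Pro": 126.7, "Ser": 92.8, "Tyr": 93.7,
}

_DIET_DMD = {"control": 0.82, "FW": 0.85, "SMW": 0.86, "FVW": 0.78}


def _aa_gkg_dm(analyzed) -> dict[str, float]:
    """Analyzed diet AA (% as-fed) plus CP to g/kg DM."""
    dm = convert_basis(analyzed, Basis.DM)
    out = {code: pct * 10.0 for code, pct in dm.aa.items()}
    if dm.cp is not None:
        out["CP"] = dm.cp * 10.0
    return out


def default_scenario(
    seed: int = 0,
    n_pigs_per_diet: int = 9,
    noise: NoiseSpec = NoiseSpec(),
) -> TrialScenario:
    """The packaged three-trial scenario with published means as truth.

    Diet analyzed values (GE, DM, marker, P, amino acids) come from the
    packaged diet tables; diet-level true DE/ME are assembled from the
    ingredient truths through the same linear replacement structure the
    difference method inverts, so ingredient-level recovery is exact at
    zero noise by construction.
    """
    diets = load_reference_diets()
    corn = INGREDIENT_ENERGY_TRUTH["corn"]
    f_bt, f_bb, f_test = 0.669, 0.969, 0.30

    energy = []
    for name, spec in diets["energy_balance"].items():
        a = spec.analyzed
        ge_dm = a.ge / a.dm_frac
        ti_dm = spec.marker_conc / a.dm_frac
        if name == "control":
            de = f_bb * corn["de"]
            me = f_bb * corn["me"]
        else:
            truth = INGREDIENT_ENERGY_TRUTH[name]
            de = f_bt * corn["de"] + f_test * truth["de"]
            me = f_bt * corn["me"] + f_test * truth["me"]
        energy.append(
            EnergyDietTruth(
                name=name, ge=ge_dm, dm_frac=a.dm_frac, ti_pct_dm=ti_dm,
                de=de, me=me, dm_digestibility=_DIET_DMD[name],
            )
        )

    p_diets = []
    for name, spec in diets["phosphorus"].items():
        a = spec.analyzed
        ge_dm = a.ge / a.dm_frac
        p_diets.append(
            EnergyDietTruth(
                name=name, ge=ge_dm, dm_frac=a.dm_frac,
                ti_pct_dm=spec.marker_conc / a.dm_frac,
                de=0.90 * ge_dm, me=0.873 * ge_dm,   # starch-sucrose diets
                dm_digestibility=0.90,
                p_pct_dm=a.p / a.dm_frac,
                attd_p=ATTD_P_TRUTH[name],
            )
        )

    fw_aa = _aa_gkg_dm(diets["amino_acids"]["FW"].analyzed)
    endogenous = {
        n: (_SID_TRUTH_FW[n] - AID_TRUTH["FW"][n]) * fw_aa[n] / 100.0
        for n in AID_TRUTH["FW"]
    }
    ileal = []
    for name, spec in diets["amino_acids"].items():
        a = spec.analyzed
        ti_dm = 0.40 / a.dm_frac  # marker included at 0.40% of the diet as fed
        aa_gkg = _aa_gkg_dm(a)
        ileal.append(
            IlealDietTruth(
                name=name,
                ti_pct_dm=ti_dm,
                aa_diet_gkg=aa_gkg,
                aid=None if name == "n_free" else dict(AID_TRUTH[name]),
                ileal_dm_digestibility=0.80,
            )
        )

    return TrialScenario(
        energy_diets=tuple(energy),
        p_diets=tuple(p_diets),
        ileal_diets=tuple(ileal),
        endogenous_aa=endogenous,
        ingredient_truth={k: dict(v) for k, v in INGREDIENT_ENERGY_TRUTH.items()},
        basal_frac_in_test=f_bt,
        basal_frac_in_basal=f_bb,
        test_frac=f_test,
        n_pigs_per_diet=n_pigs_per_diet,
        noise=noise,
        seed=seed,
    )


def with_seed(sc: TrialScenario, seed: int) -> TrialScenario:
    """Copy of a scenario with a different seed."""
    return replace(sc, seed=seed)
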
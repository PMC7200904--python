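"""Three-step in vitro digestion calculus.

A feed sample is hydrolyzed with pepsin then pancreatin (simulating
gastric and small-intestinal digestion); the residue is fermented with a
fecal inoculum (simulating the hindgut).  DM disappearance in each step
gives the hydrolysis (IVHDMD) and fermentation (IVFDMD) digestibilities,
combined into total-tract DM digestibility by applying the fermentation
coefficient to the DM that survived hydrolysis:

    total = IVHDMD + (100 - IVHDMD) x IVFDMD / 100

In vitro digestible energy charges the energy of the hydrolysis residue
against the sample's gross energy and credits back the combustion energy
of the volatile fatty acids (VFA) produced during fermentation, all per
kg of original sample DM.  Cumulative gas-production readings are stored
for plotting but deliberately never fitted with a kinetic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple


class MassBalanceError(ValueError):
    """Residue mass or energy bookkeeping violates conservation."""


#: Combustion energy of fermentation acids, kcal/mol.
VFA_ENERGY_KCAL_PER_MOL = {
    "acetate": 209.0,
    "propionate": 365.0,
    "butyrate": 522.0,
    "valerate": 678.0,
}


@dataclass(frozen=True)
class VFAProfile:
    """Volatile fatty acids produced, mol per kg of original sample DM."""

    acetate: float = 0.0
    propionate: float = 0.0
    butyrate: float = 0.0
    valerate: float = 0.0

    def __post_init__(self):
        for acid in VFA_ENERGY_KCAL_PER_MOL:
            v = getattr(self, acid)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{acid} = {v} mol/kg must be finite and >= 0")

    @classmethod
    def from_supernatant(
        cls,
        mmol_per_l: dict[str, float],
        supernatant_volume_ml: float,
        sample_dm_g: float,
    ) -> "VFAProfile":
        """Convert assayed supernatant concentrations (mmol/L) to mol per kg
        of fermented sample DM, given the incubation volume and substrate
        mass (e.g. 30 mL of buffered inoculum on 200 mg of residue)."""
        if supernatant_volume_ml <= 0 or sample_dm_g <= 0:
            raise ValueError("volume and sample mass must be positive")
        factor = (supernatant_volume_ml / 1000.0) / 1000.0 / (sample_dm_g / 1000.0)
        return cls(**{k: v * factor for k, v in mmol_per_l.items()})


def ivdmd(mass_before: float, residue_after: float) -> float:
    """In vitro DM disappearance, %, of one hydrolysis or fermentation step."""
    if mass_before <= 0:
        raise MassBalanceError(f"sample mass must be positive, got {mass_before}")
    if residue_after < 0 or residue_after > mass_before:
        raise MassBalanceError(
            f"residue ({residue_after} g) outside [0, sample mass {mass_before} g]"
        )
    return 100.0 * (mass_before - residue_after) / mass_before


def total_tract_dmd(ivhdmd: float, ivfdmd: float) -> float:
    """Combined total-tract DM digestibility, %, from the two steps.

    Fermentation acts only on DM that escaped hydrolysis, so
    total = ivhdmd + (100 - ivhdmd) x ivfdmd / 100.  Bounded below by
    the hydrolysis value and above by 100.
    """
    for name, v in (("ivhdmd", ivhdmd), ("ivfdmd", ivfdmd)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} = {v} outside [0, 100]")
    return ivhdmd + (100.0 - ivhdmd) * ivfdmd / 100.0


def vfa_energy(profile: VFAProfile) -> float:
    """Energy released as VFA, kcal per kg of original sample DM.

    Molar combustion energies: acetate 209, propionate 365, butyrate 522,
    valerate 678 kcal/mol.
    """
    return sum(
        getattr(profile, acid) * kcal for acid, kcal in VFA_ENERGY_KCAL_PER_MOL.items()
    )


def invitro_de(
    ge_sample: float,
    residue_fraction: float,
    ge_residue: float,
    vfa_kcal: float,
) -> float:
    """In vitro total-tract DE, kcal per kg of original sample DM.

    DE = GE_sample - residue_fraction x GE_residue + VFA energy, where
    ``residue_fraction`` is the hydrolysis residue's share of the original
    sample DM so that the residue's energy density (kcal/kg residue DM) is
    charged on the original-sample scale.
    """
    if not (0.0 <= residue_fraction <= 1.0):
        raise MassBalanceError(f"residue_fraction = {residue_fraction} outside [0, 1]")
    if ge_sample < 0 or ge_residue < 0 or vfa_kcal < 0:
        raise MassBalanceError("energies must be >= 0")
    de = ge_sample - residue_fraction * ge_residue + vfa_kcal
    if de > ge_sample + vfa_kcal + 1e-9:
        raise MassBalanceError("in vitro DE exceeds sample GE plus VFA energy")
    return de


@dataclass(frozen=True)
class InVitroResult:
    """Assembled outcome of the three-step assay for one sample."""

    sample: str
    mass_pre_hydrolysis: float          # g DM
    residue_mass_hydrolysis: float      # g DM
    ivhdmd: float                       # %
    ivfdmd: float                       # %
    ivdmd_total: float                  # %
    ge_sample: float                    # kcal/kg sample DM
    ge_residue: float                   # kcal/kg residue DM
    vfa: VFAProfile
    de: float                           # kcal/kg sample DM
    om_digestibility: Optional[float] = None  # OMdv, g/kg DM
    gas_curve: Sequence[Tuple[float, float]] = field(default_factory=tuple)  # (h, mL)


def assemble_invitro(
    sample: str,
    mass_pre_hydrolysis: float,
    residue_mass_hydrolysis: float,
    fermentation_mass: float,
    fermentation_residue: float,
    ge_sample: float,
    ge_residue: float,
    vfa: VFAProfile,
    om_digestibility: Optional[float] = None,
    gas_curve: Sequence[Tuple[float, float]] = (),
) -> InVitroResult:
    """Run the full in vitro bookkeeping for one sample.

    ``fermentation_mass``/``fermentation_residue`` are the DM weights of
    the hydrolysis residue subsample put to fermentation and what remains
    of it, from which IVFDMD is computed.
    """
    hyd = ivdmd(mass_pre_hydrolysis, residue_mass_hydrolysis)
    ferm = ivdmd(fermentation_mass, fermentation_residue)
    total = total_tract_dmd(hyd, ferm)
    residue_fraction = residue_mass_hydrolysis / mass_pre_hydrolysis
    de = invitro_de(ge_sample, residue_fraction, ge_residue, vfa_energy(vfa))
    return InVitroResult(
        sample=sample,
        mass_pre_hydrolysis=mass_pre_hydrolysis,
        residue_mass_hydrolysis=residue_mass_hydrolysis,
        ivhdmd=hyd,
        ivfdmd=ferm,
        ivdmd_total=total,
        ge_sample=ge_sample,
        ge_residue=ge_residue,
        vfa=vfa,
        de=de,
        om_digestibility=om_digestibility,
        gas_curve=tuple(gas_curve),
    )
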
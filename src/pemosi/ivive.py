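"""In vitro -> in vivo extrapolation of potencies and growth rates.

In vitro potencies are measured in protein-poor culture medium; plasma
potencies are inferred by assuming equal *unbound* drug concentrations
in both matrices and correcting for the free-fraction difference:

    EC50_plasma = EC50_medium * fu_medium / fu_plasma
    fu_medium   = 1 / (1 + (Pmedium/Pplasma) * (1 - fu_plasma)/fu_plasma)

with plasma protein assumed ``protein_ratio`` (default 10) times more
concentrated than medium protein.  Molar in vitro potencies are
converted to the mass scales used by the plasma PK (ug/L for
osimertinib, mg/L for pemetrexed) via the molecular weight.

The in vitro exponential growth rate is related to the in vivo
Simeoni exponential rate by a fixed scaling factor of 4.736.
"""

from __future__ import annotations

from dataclasses import dataclass

GROWTH_SCALE_IN_VITRO = 4.736

#: molecular weights, g/mol (free-acid pemetrexed; osimertinib free base)
MW_PEM = 427.4
MW_OSI = 499.6


@dataclass(frozen=True)
class BindingContext:
    fu_plasma: float             # unbound fraction in plasma
    protein_ratio: float = 10.0  # Pplasma / Pmedium

    def __post_init__(self) -> None:
        if not (0 < self.fu_plasma <= 1):
            raise ValueError(f"fu_plasma must be in (0, 1], "
                             f"got {self.fu_plasma!r}")
        if self.protein_ratio <= 0:
            raise ValueError("protein_ratio must be > 0")


@dataclass(frozen=True)
class DrugIdentity:
    name: str
    molecular_weight: float      # g/mol

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")


PEM = DrugIdentity("pemetrexed", MW_PEM)
OSI = DrugIdentity("osimertinib", MW_OSI)


def fu_medium(ctx: BindingContext) -> float:
    """Unbound fraction in culture medium implied by the plasma one."""
    fp = ctx.fu_plasma
    return 1.0 / (1.0 + (1.0 / ctx.protein_ratio) * (1.0 - fp) / fp)


def molar_to_mass(conc_nM: float, drug: DrugIdentity) -> float:
    """nM -> ug/L (== ng/mL).  1 nM = MW ng/L = MW/1000 ug/L."""
    if conc_nM < 0:
        raise ValueError("concentration must be >= 0")
    return conc_nM * drug.molecular_weight / 1000.0


def mass_to_molar(conc_ug_L: float, drug: DrugIdentity) -> float:
    """ug/L -> nM (inverse of :func:`molar_to_mass`)."""
    if conc_ug_L < 0:
        raise ValueError("concentration must be >= 0")
    return conc_ug_L * 1000.0 / drug.molecular_weight


def ec50_to_plasma(ec50_medium_nM: float, ctx: BindingContext,
                   drug: DrugIdentity) -> float:
    """Free-fraction-corrected plasma potency in ug/L.

    Applies the medium->plasma unbound-fraction ratio and converts from
    nM to mass units.
    """
    if ec50_medium_nM <= 0:
        raise ValueError("ec50_medium must be > 0")
    ec50_plasma_nM = ec50_medium_nM * fu_medium(ctx) / ctx.fu_plasma
    return molar_to_mass(ec50_plasma_nM, drug)


def scale_growth_rate(lambda0_in_vivo: float) -> tuple[float, float]:
    """(rate per day, rate per hour) of in vitro exponential growth.

    ``lambda0_in_vitro = 4.736 * lambda0_in_vivo`` (both 1/day); the
    hourly value is the same rate divided by 24.
    """
    if lambda0_in_vivo <= 0:
        raise ValueError("lambda0_in_vivo must be > 0")
    per_day = GROWTH_SCALE_IN_VITRO * lambda0_in_vivo
    return per_day, per_day / 24.0
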
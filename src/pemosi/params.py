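"""Parameter containers for the PK-PD model.

Rates are stored in the units they are conventionally reported in
(plasma PK rates in 1/h; receptor/tumor turnover and growth rates in
1/day) and converted to a single internal hourly scale when packed for
the ODE engine.  Concentration scales follow the plasma potencies:
pemetrexed (PEM) in mg/L, osimertinib (OSI) in ug/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np

HOURS_PER_DAY = 24.0


def _positive(name: str, value: float, problems: list[str]) -> None:
    if not np.isfinite(value) or value <= 0:
        problems.append(f"{name} must be finite and > 0, got {value!r}")


def _nonnegative(name: str, value: float, problems: list[str]) -> None:
    if not np.isfinite(value) or value < 0:
        problems.append(f"{name} must be finite and >= 0, got {value!r}")


def _raise_if(problems: list[str], cls: str) -> None:
    if problems:
        raise ValueError(f"invalid {cls}: " + "; ".join(problems))


@dataclass(frozen=True)
class PemPKParams:
    """Two-compartment i.p. PK of pemetrexed (per-kg basis, rates 1/h)."""

    ka_pem: float = 6.0          # absorption from the peritoneal depot, 1/h
    V1_pem: float = 0.5          # central volume, L/kg
    k12_pem: float = 0.2         # central->peripheral, 1/h
    k21_pem: float = 3.0         # peripheral->central, 1/h
    kel_pem: float = 1.3         # elimination (renal), 1/h
    F_pem: float = 1.0           # i.p. bioavailability, fixed 1

    def __post_init__(self) -> None:
        p: list[str] = []
        for name in ("ka_pem", "V1_pem", "k12_pem", "k21_pem", "kel_pem"):
            _positive(name, getattr(self, name), p)
        if not (0 < self.F_pem <= 1):
            p.append(f"F_pem must be in (0, 1], got {self.F_pem!r}")
        _raise_if(p, "PemPKParams")


@dataclass(frozen=True)
class OsiPKParams:
    """Two-compartment oral PK of osimertinib (apparent V/F basis)."""

    ka_osi: float = 1.0          # first-order absorption, 1/h
    Fa_osi: float = 0.7          # oral bioavailability fraction
    V1_osi: float = 7.0          # apparent central volume (V/F basis), L/kg
    k12_osi: float = 0.1         # 1/h
    k21_osi: float = 0.2         # 1/h
    kel_osi: float = 0.15        # 1/h

    def __post_init__(self) -> None:
        p: list[str] = []
        for name in ("ka_osi", "V1_osi", "k12_osi", "k21_osi", "kel_osi"):
            _positive(name, getattr(self, name), p)
        if not (0 < self.Fa_osi <= 1):
            p.append(f"Fa_osi must be in (0, 1], got {self.Fa_osi!r}")
        _raise_if(p, "OsiPKParams")


@dataclass(frozen=True)
class FolatePDParams:
    """Indirect-response cascade: PEM stimulates loss of folate-metabolising
    enzymes; folate synthesis follows the enzyme pool."""

    kout_enzyme: float = 0.12    # enzyme turnover, 1/h
    kout_folate: float = 0.12    # folate turnover, 1/h
    Emax_pem: float = 10.0       # max stimulation of enzyme loss
    EC50_pem: float = 0.47315    # PEM plasma potency, mg/L
    gamma_enzyme: float = 1.5    # enzyme->folate transduction exponent

    def __post_init__(self) -> None:
        p: list[str] = []
        _positive("kout_enzyme", self.kout_enzyme, p)
        _positive("kout_folate", self.kout_folate, p)
        _nonnegative("Emax_pem", self.Emax_pem, p)
        _positive("EC50_pem", self.EC50_pem, p)
        _positive("gamma_enzyme", self.gamma_enzyme, p)
        _raise_if(p, "FolatePDParams")


@dataclass(frozen=True)
class EgfrPDParams:
    """EGFR-signal turnover: OSI stimulates inactivation; damaged tumor
    cells feed back on synthesis (signal rebound)."""

    kout_EGFR: float = 1.5       # turnover, 1/day (converted internally)
    Imax_osi: float = 14.0       # max stimulation of EGFR inactivation
    EC50_osi: float = 48.86      # OSI plasma potency, ug/L
    gamma_osi: float = 1.0       # Hill coefficient
    k_feedback: float = 0.3      # damage-driven synthesis gain (fraction scale)
    gamma_feedback: float = 2.0  # feedback exponent

    def __post_init__(self) -> None:
        p: list[str] = []
        _positive("kout_EGFR", self.kout_EGFR, p)
        _nonnegative("Imax_osi", self.Imax_osi, p)
        _positive("EC50_osi", self.EC50_osi, p)
        _positive("gamma_osi", self.gamma_osi, p)
        _nonnegative("k_feedback", self.k_feedback, p)
        _positive("gamma_feedback", self.gamma_feedback, p)
        _raise_if(p, "EgfrPDParams")


@dataclass(frozen=True)
class TGIParams:
    """Four-compartment tumor growth-inhibition module (Simeoni-type)."""

    lambda0: float = 0.1032      # exponential growth rate, 1/day
    lambda1: float = 51.08       # linear growth rate, mm^3/day
    psi: float = 20.0            # exponential/linear switching exponent
    k1: float = 0.05             # natural proliferating->damaged rate, 1/day
    k2: float = 0.02             # damaged-transit/death rate, 1/day
    Emax_folate: float = 13.0    # max folate-deficit kill amplification
    EC50_folate: float = 0.5     # potency on the (1-Folate) deficit scale
    gamma_folate: float = 5.0    # Hill exponent on the folate deficit
    gamma_EGFR: float = 1.0      # EGFR->proliferation exponent
    gamma_G1: float = 0.97        # EGFR->transition-gating exponent (G1 arrest)
    k_bim: float = 211.0         # apoptosis amplification gain (wild-type Bim)
    gamma_bim: float = 0.4       # apoptosis exponent
    V0: float = 200.0            # initial tumor volume, mm^3

    def __post_init__(self) -> None:
        p: list[str] = []
        for name in ("lambda0", "lambda1", "k1", "k2", "psi",
                     "gamma_folate", "gamma_EGFR", "gamma_G1", "gamma_bim",
                     "V0"):
            _positive(name, getattr(self, name), p)
        _nonnegative("Emax_folate", self.Emax_folate, p)
        _nonnegative("k_bim", self.k_bim, p)
        if not (0 < self.EC50_folate <= 1):
            p.append(f"EC50_folate must be in (0, 1], got {self.EC50_folate!r}")
        _raise_if(p, "TGIParams")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter bundle for the coupled PK-PD system."""

    pem: PemPKParams = field(default_factory=PemPKParams)
    osi: OsiPKParams = field(default_factory=OsiPKParams)
    folate: FolatePDParams = field(default_factory=FolatePDParams)
    egfr: EgfrPDParams = field(default_factory=EgfrPDParams)
    tgi: TGIParams = field(default_factory=TGIParams)

    def with_updates(self, **named: float) -> "ModelParams":
        """Return a copy with individual leaf parameters replaced.

        Names are the flat field names, e.g. ``with_updates(k_bim=21.1)``.
        """
        blocks = {"pem": self.pem, "osi": self.osi, "folate": self.folate,
                  "egfr": self.egfr, "tgi": self.tgi}
        remaining = dict(named)
        for key, block in blocks.items():
            hits = {n: remaining.pop(n) for n in list(remaining)
                    if n in {f.name for f in fields(block)}}
            if hits:
                blocks[key] = replace(block, **hits)
        if remaining:
            raise KeyError(f"unknown parameter name(s): {sorted(remaining)}")
        return ModelParams(**blocks)

    def leaf_items(self) -> Iterator[tuple[str, float]]:
        for block in (self.pem, self.osi, self.folate, self.egfr, self.tgi):
            for f in fields(block):
                yield f.name, getattr(block, f.name)

    def get(self, name: str) -> float:
        for key, value in self.leaf_items():
            if key == name:
                return value
        raise KeyError(name)


# ----------------------------------------------------------------------
# Packing to the internal hourly vector consumed by the ODE engine.
# ----------------------------------------------------------------------

PACK_NAMES = (
    "ka_pem", "V1_pem", "k12_pem", "k21_pem", "kel_pem", "F_pem",
    "ka_osi", "Fa_osi", "V1F_osi", "k12_osi", "k21_osi", "kel_osi",
    "kout_enzyme", "kout_folate", "Emax_pem", "EC50_pem", "gamma_enzyme",
    "kout_EGFR", "Imax_osi", "EC50_osi", "gamma_osi",
    "k_feedback", "gamma_feedback",
    "lambda0", "lambda1", "psi", "k1", "k2",
    "Emax_folate", "EC50_folate", "gamma_folate",
    "gamma_EGFR", "gamma_G1", "k_bim", "gamma_bim",
)
PACK_INDEX = {name: i for i, name in enumerate(PACK_NAMES)}
N_PACK = len(PACK_NAMES)

#: leaf parameters that are stored per-day and divided by 24 when packed
_DAILY_RATES = {"kout_EGFR", "lambda0", "lambda1", "k1", "k2"}


def pack(params: ModelParams) -> np.ndarray:
    """Flatten a :class:`ModelParams` into the engine's hourly vector.

    ``V1F_osi`` is the apparent central volume V1/Fa used in the
    concentration relation C = X1 / (V1/Fa).
    """
    v = np.empty(N_PACK)
    pem, osi, fol, eg, tg = (params.pem, params.osi, params.folate,
                             params.egfr, params.tgi)
    v[0:6] = (pem.ka_pem, pem.V1_pem, pem.k12_pem, pem.k21_pem,
              pem.kel_pem, pem.F_pem)
    v[6:12] = (osi.ka_osi, osi.Fa_osi, osi.V1_osi / osi.Fa_osi,
               osi.k12_osi, osi.k21_osi, osi.kel_osi)
    v[12:17] = (fol.kout_enzyme, fol.kout_folate, fol.Emax_pem,
                fol.EC50_pem, fol.gamma_enzyme)
    v[17:23] = (eg.kout_EGFR / HOURS_PER_DAY, eg.Imax_osi, eg.EC50_osi,
                eg.gamma_osi, eg.k_feedback, eg.gamma_feedback)
    v[23:35] = (tg.lambda0 / HOURS_PER_DAY, tg.lambda1 / HOURS_PER_DAY,
                tg.psi, tg.k1 / HOURS_PER_DAY, tg.k2 / HOURS_PER_DAY,
                tg.Emax_folate, tg.EC50_folate, tg.gamma_folate,
                tg.gamma_EGFR, tg.gamma_G1, tg.k_bim, tg.gamma_bim)
    return v


def pack_population(base: ModelParams,
                    overrides: dict[str, np.ndarray]) -> np.ndarray:
    """Pack a batch of parameter sets sharing ``base`` structure.

    ``overrides`` maps flat leaf names to per-subject arrays *in the
    leaf's native units* (per-day rates given per day, etc.).  Returns
    an array of shape ``(N_PACK, n)``.
    """
    v0 = pack(base)
    n = max((np.asarray(a).size for a in overrides.values()), default=1)
    V = np.tile(v0[:, None], (1, n))
    for name, values in overrides.items():
        arr = np.asarray(values, dtype=float)
        if name == "V1_osi":
            V[PACK_INDEX["V1F_osi"]] = arr / base.osi.Fa_osi
            continue
        if name not in PACK_INDEX:
            raise KeyError(f"cannot pack override for {name!r}")
        if name in _DAILY_RATES:
            arr = arr / HOURS_PER_DAY
        V[PACK_INDEX[name]] = arr
    return V
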
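"""Synthetic-data generators with known ground truth.

Every input the calibration pipeline consumes can be generated here:
per-animal tumor-volume curves (log-normal noise), two-compartment
plasma concentration profiles (proportional error, with the study's
sparse pooled-sampling mode), EGFR signal-recovery curves, 4PL
dose-response tables and virtual cohorts.  Each generator is a
deterministic function of (parameters, seed) and returns the noisy
data together with a serialisable :class:`GroundTruth` side-car.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .calibration import TimeSeries, four_pl, two_compartment_profile
from .model import simulate
from .params import ModelParams
from .regimen import Regimen
from .scenarios import PopulationSpec, draw_cohort

#: default assay noise: proportional 15% for PK, log-normal 20% for
#: tumor volumes, additive 5% of baseline for normalised WB-like signals
PK_NOISE_CV = 0.15
TUMOR_NOISE_CV = 0.20
SIGNAL_NOISE_SD = 0.05


@dataclass(frozen=True)
class NoiseModel:
    kind: str = "none"        # none | additive_gaussian | proportional | lognormal
    cv_or_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive_gaussian", "proportional",
                             "lognormal"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv_or_sd < 0:
            raise ValueError("noise magnitude must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator
              ) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "none" or self.cv_or_sd == 0:
            return v.copy()
        if self.kind == "additive_gaussian":
            return v + rng.normal(0.0, self.cv_or_sd, v.shape)
        if self.kind == "proportional":
            return v * (1.0 + rng.normal(0.0, self.cv_or_sd, v.shape))
        sigma = np.sqrt(np.log(1.0 + self.cv_or_sd ** 2))
        return v * np.exp(rng.normal(0.0, sigma, v.shape))


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate a dataset bit-for-bit."""
    generator: str
    parameters: dict[str, Any]
    noise: NoiseModel
    seed: int
    child_seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, default=float, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["noise"] = NoiseModel(**d["noise"])
        return cls(**d)


def _spawn(seed: int, n: int) -> list[int]:
    """Deterministic per-stream child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


# ----------------------------------------------------------------------

def gen_tumor_curves(params: ModelParams, regimen: Regimen,
                     sample_days=None, noise: NoiseModel | None = None,
                     n_animals: int = 5,
                     engine_name: str = "lsoda"
                     ) -> tuple[list[TimeSeries], GroundTruth]:
    """Per-animal tumor-volume series on an every-3-days grid."""
    if noise is None:
        noise = NoiseModel("lognormal", TUMOR_NOISE_CV, seed=0)
    t_end = regimen.end_time
    if sample_days is None:
        sample_days = np.arange(0.0, t_end / 24.0 + 1e-9, 3.0)
    sample_days = np.asarray(sample_days, dtype=float)
    if sample_days[-1] * 24.0 > t_end + 1e-9:
        raise ValueError("sample days extend beyond the regimen horizon")
    grid = sample_days * 24.0
    traj = simulate(regimen, params, t_end=t_end, output_grid=grid,
                    engine_name=engine_name)
    seeds = _spawn(noise.seed, n_animals)
    series = []
    for s in seeds:
        rng = np.random.default_rng(s)
        series.append(TimeSeries(times=grid,
                                 values=noise.apply(traj.volume, rng),
                                 unit="mm^3"))
    truth = GroundTruth(
        generator="gen_tumor_curves",
        parameters={"model": dict(params.leaf_items()),
                    "strategy": regimen.strategy_label,
                    "interval_h": regimen.interval_h,
                    "n_cycles": regimen.n_cycles,
                    "sample_days": sample_days.tolist(),
                    "n_animals": n_animals},
        noise=noise, seed=noise.seed,
        child_seeds={f"animal_{i}": s for i, s in enumerate(seeds)})
    return series, truth


def gen_pk_profiles(pk_kwargs: dict[str, float], dose: float, route: str,
                    times, noise: NoiseModel | None = None,
                    n_subgroups: int = 1
                    ) -> tuple[TimeSeries | list[TimeSeries], GroundTruth]:
    """Two-compartment concentration profile(s) with proportional error.

    ``pk_kwargs`` holds ka/V1/k12/k21/kel (ka ignored for iv).  With
    ``n_subgroups > 1`` the schedule is split round-robin into sparse
    subgroup curves emulating pooled serial sampling.
    """
    if noise is None:
        noise = NoiseModel("proportional", PK_NOISE_CV, seed=0)
    times = np.asarray(times, dtype=float)
    conc = two_compartment_profile(times, dose, pk_kwargs.get("ka", 0.0),
                                   pk_kwargs["V1"], pk_kwargs["k12"],
                                   pk_kwargs["k21"], pk_kwargs["kel"],
                                   route=route)
    seeds = _spawn(noise.seed, max(n_subgroups, 1))
    truth = GroundTruth(
        generator="gen_pk_profiles",
        parameters={"pk": dict(pk_kwargs), "dose": dose, "route": route,
                    "times_h": times.tolist(), "n_subgroups": n_subgroups},
        noise=noise, seed=noise.seed,
        child_seeds={f"subgroup_{i}": s for i, s in enumerate(seeds)})
    if n_subgroups <= 1:
        rng = np.random.default_rng(seeds[0])
        return TimeSeries(times, noise.apply(conc, rng), unit="conc"), truth
    out = []
    for g, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        sel = np.arange(len(times)) % n_subgroups == g
        out.append(TimeSeries(times[sel], noise.apply(conc[sel], rng),
                              unit="conc"))
    return out, truth


RECOVERY_GRID_H = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0)


def gen_recovery_and_doseresponse(kout_day: float, ec50_nM: float,
                                  hill: float = 1.0,
                                  recovery_grid_h=RECOVERY_GRID_H,
                                  conc_grid_nM=None,
                                  noise: NoiseModel | None = None
                                  ) -> tuple[TimeSeries, pd.DataFrame,
                                             GroundTruth]:
    """EGFR-recovery curve and a 4PL inhibition table.

    The recovery curve is 1 - exp(-kout t) from a fully depleted
    baseline; the dose-response table is the normalised pEGFR/EGFR
    signal 1/(1+(c/EC50)^hill) on a log-spaced concentration grid.
    """
    if noise is None:
        noise = NoiseModel("additive_gaussian", SIGNAL_NOISE_SD, seed=0)
    t = np.asarray(recovery_grid_h, dtype=float)
    if conc_grid_nM is None:
        conc_grid_nM = np.geomspace(ec50_nM / 30.0, ec50_nM * 30.0, 9)
    conc = np.asarray(conc_grid_nM, dtype=float)
    rec_true = 1.0 - np.exp(-kout_day * t / 24.0)
    # remaining signal = 1 - fractional inhibition (4PL from 0 to 1)
    dr_true = 1.0 - four_pl(conc, 0.0, 1.0, ec50_nM, hill)
    s_rec, s_dr = _spawn(noise.seed, 2)
    rec = TimeSeries(t, noise.apply(rec_true, np.random.default_rng(s_rec)),
                     unit="normalized signal")
    dr = pd.DataFrame({
        "conc_nM": conc,
        "signal": noise.apply(dr_true, np.random.default_rng(s_dr))})
    truth = GroundTruth(
        generator="gen_recovery_and_doseresponse",
        parameters={"kout_day": kout_day, "ec50_nM": ec50_nM, "hill": hill,
                    "recovery_grid_h": list(t),
                    "conc_grid_nM": conc.tolist()},
        noise=noise, seed=noise.seed,
        child_seeds={"recovery": s_rec, "doseresponse": s_dr})
    return rec, dr, truth


def gen_virtual_cohort(spec: PopulationSpec, params: ModelParams
                       ) -> tuple[pd.DataFrame, GroundTruth]:
    """Subject parameter table (genotype two-point + log-normal IIV)."""
    cohort = draw_cohort(spec, params)
    truth = GroundTruth(
        generator="gen_virtual_cohort",
        parameters={"model": dict(params.leaf_items()),
                    "spec": dataclasses.asdict(spec)},
        noise=NoiseModel("lognormal", spec.iiv_cv, seed=spec.seed),
        seed=spec.seed)
    return cohort, truth
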
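"""Interval optimisation, perturbation scenarios, Sobol GSA and
Monte Carlo virtual-population simulation."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sobol as sobol_
from .model import Trajectory, derived_metrics, simulate, simulate_batch
from .params import ModelParams, pack_population
from .regimen import Regimen, build_regimen

#: PD and tumor-dynamics parameters subject to sensitivity analysis and
#: inter-individual variability (PK and the structural psi/V0 are not).
PD_PARAMETERS = (
    "kout_enzyme", "kout_folate", "Emax_pem", "EC50_pem", "gamma_enzyme",
    "kout_EGFR", "Imax_osi", "EC50_osi", "gamma_osi",
    "k_feedback", "gamma_feedback",
    "k1", "k2", "Emax_folate", "EC50_folate", "gamma_folate",
    "gamma_EGFR", "gamma_G1", "k_bim", "gamma_bim",
)
IIV_PARAMETERS = PD_PARAMETERS + ("lambda0", "lambda1")

#: GSA sampling ranges: 0.5-2x baseline, except 2/3-3/2x for
#: Emax_folate and kout_enzyme.
DEFAULT_RANGE_FACTORS = {
    name: ((2 / 3, 3 / 2) if name in ("Emax_folate", "kout_enzyme")
           else (0.5, 2.0))
    for name in PD_PARAMETERS
}


# ----------------------------------------------------------------------
# interval comparison and perturbation scenarios
# ----------------------------------------------------------------------

def _regimen_for_interval(interval_h: float, n_cycles: int,
                          cycle_length_days: float) -> Regimen:
    if interval_h == 0:
        return build_regimen("concurrent", n_cycles=n_cycles,
                             cycle_length_days=cycle_length_days)
    return build_regimen("sequential", interval_h=interval_h,
                         n_cycles=n_cycles,
                         cycle_length_days=cycle_length_days)


def compare_intervals(params: ModelParams, intervals,
                      t_end: float | None = None,
                      n_cycles: int = 3, cycle_length_days: float = 7.0,
                      engine_name: str = "lsoda") -> dict:
    """Simulate sequential regimens over a list of start intervals (h).

    Interval 0 means concurrent dosing.  Returns per-interval final
    volumes plus full metric tables against a shared control.
    """
    control = simulate(build_regimen("control", n_cycles=n_cycles,
                                     cycle_length_days=cycle_length_days),
                       params, t_end=t_end, engine_name=engine_name)
    out = {"intervals_h": list(intervals), "final_volume": {},
           "total_dead": {}, "metrics": {}, "control": control,
           "trajectories": {}}
    for iv in intervals:
        reg = _regimen_for_interval(iv, n_cycles, cycle_length_days)
        traj = simulate(reg, params, t_end=t_end, engine_name=engine_name)
        met = derived_metrics(traj, control)
        out["final_volume"][iv] = float(traj.volume[-1])
        out["total_dead"][iv] = float(traj.cum_dead[-1])
        out["metrics"][iv] = met
        out["trajectories"][iv] = traj
    return out


def perturb_scenario(params: ModelParams, modifications: dict[str, float],
                     interval_h: float = 48.0, n_cycles: int = 3,
                     cycle_length_days: float = 7.0,
                     engine_name: str = "lsoda") -> dict:
    """Sequential-vs-concurrent endpoint gap before/after perturbation.

    ``modifications`` maps flat parameter names to positive multipliers
    (e.g. ``{"EC50_osi": 5, "Imax_osi": 0.2}`` for reduced OSI
    sensitivity).  The gap is sequential minus concurrent endpoint
    volume; a shrinking |gap| means the scheduling advantage is lost.
    """
    if any(m <= 0 for m in modifications.values()):
        raise ValueError("multipliers must be > 0")
    modified = params.with_updates(
        **{k: params.get(k) * m for k, m in modifications.items()})
    seq_reg = _regimen_for_interval(interval_h, n_cycles, cycle_length_days)
    con_reg = _regimen_for_interval(0.0, n_cycles, cycle_length_days)
    result: dict = {"trajectories": {}}
    for tag, p in (("baseline", params), ("modified", modified)):
        seq = simulate(seq_reg, p, engine_name=engine_name)
        con = simulate(con_reg, p, engine_name=engine_name)
        result["trajectories"][tag] = {"sequential": seq, "concurrent": con}
        result[f"gap_{tag}"] = float(seq.volume[-1] - con.volume[-1])
    return result


# ----------------------------------------------------------------------
# Sobol GSA on the day-18 TGI%
# ----------------------------------------------------------------------

def _tgi_day18_batch(params: ModelParams, regimen: Regimen,
                     day: float = 18.0, steps_per_hour: int = 16):
    """Return a vectorised evaluator mapping parameter matrices to TGI%.

    The control arm of each draw shares that draw's growth and natural
    k1/k2 cycle so the TGI% isolates drug effect.
    """
    t_end = day * 24.0
    grid = np.array([0.0, t_end])
    control = Regimen(events=(), strategy_label="control",
                      n_cycles=regimen.n_cycles,
                      cycle_length_days=regimen.cycle_length_days)

    def evaluate(X: np.ndarray, names: list[str]) -> np.ndarray:
        overrides = {name: X[:, j] for j, name in enumerate(names)}
        P = pack_population(params, overrides)
        V0 = params.tgi.V0
        treated = simulate_batch(regimen, P, V0, grid,
                                 steps_per_hour=steps_per_hour)
        ctrl = simulate_batch(control, P, V0, grid,
                              steps_per_hour=steps_per_hour)
        vt = treated[-1, :, 9:13].sum(axis=1)
        vc = ctrl[-1, :, 9:13].sum(axis=1)
        return (1.0 - vt / vc) * 100.0

    return evaluate


def sobol_gsa(spec: sobol_.SobolSpec, params: ModelParams,
              regimen: Regimen, day: float = 18.0,
              steps_per_hour: int = 16,
              n_boot: int = 200) -> sobol_.SobolResult:
    """Sobol indices of the day-``day`` TGI% under a dosing regimen."""
    names = spec.names
    base = np.array([spec.parameters[n] for n in names])
    fac = np.array([spec.range_factors[n] for n in names])
    bounds = base[:, None] * fac
    evaluator = _tgi_day18_batch(params, regimen, day=day,
                                 steps_per_hour=steps_per_hour)
    result = sobol_.sobol_indices(
        lambda X: evaluator(X, names), bounds, spec.n_samples,
        seed=spec.seed, n_boot=n_boot)
    result.names = names
    return result


def default_sobol_spec(params: ModelParams, n_samples: int = 1000,
                       seed: int = 0) -> sobol_.SobolSpec:
    baselines = {name: params.get(name) for name in PD_PARAMETERS}
    return sobol_.SobolSpec(parameters=baselines,
                            range_factors=dict(DEFAULT_RANGE_FACTORS),
                            n_samples=n_samples, seed=seed)


# ----------------------------------------------------------------------
# virtual population
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    n_subjects: int = 2000
    iiv_cv: float = 0.30                 # log-normal CV on PD parameters
    bim_del_prevalence: float = 0.115    # BIM-deletion carrier fraction
    bim_del_kbim: float = 21.1           # k_bim in deleted genotype
    bim_del_gamma_factor: float = 5.0    # multiplier on gamma_bim if deleted
    horizon_days: float = 210.0
    response_threshold: float = 0.70     # RECIST-like volume fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.bim_del_prevalence <= 1):
            raise ValueError("prevalence must be in [0, 1]")
        if self.iiv_cv < 0:
            raise ValueError("iiv_cv must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class PopulationResult:
    spec: PopulationSpec
    times: np.ndarray                       # h
    subject_params: pd.DataFrame            # one row per subject
    volume_curves: dict[str, np.ndarray]    # label -> (n_t, n)
    responder_curves: dict[str, np.ndarray]  # label -> ORR(t)
    time_averaged_orr: dict[str, float]
    percentile_bands: dict[str, np.ndarray]  # label -> (3, n_t): 5/50/95th
    excluded: dict[str, int] = field(default_factory=dict)


def draw_cohort(spec: PopulationSpec, params: ModelParams) -> pd.DataFrame:
    """Per-subject parameter table: genotype two-point distribution on
    (k_bim, gamma_bim) followed by log-normal IIV on all PD and growth
    parameters.

    The log-normal is median-preserving: theta_i = theta*exp(eta),
    eta ~ N(0, ln(1+CV^2)).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    deleted = rng.random(n) < spec.bim_del_prevalence
    sigma = math.sqrt(math.log(1.0 + spec.iiv_cv ** 2))
    table: dict[str, np.ndarray] = {
        "genotype": np.where(deleted, "BIM-del", "wild-type")}
    for name in IIV_PARAMETERS:
        if name == "k_bim":
            typical = np.where(deleted, spec.bim_del_kbim, params.get(name))
        elif name == "gamma_bim":
            typical = np.where(deleted,
                               params.get(name) * spec.bim_del_gamma_factor,
                               params.get(name))
        else:
            typical = np.full(n, params.get(name))
        eta = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
        drawn = typical * np.exp(eta)
        if name == "EC50_folate":
            # potency on the (1-Folate) deficit fraction: bounded by 1
            drawn = np.minimum(drawn, 1.0)
        table[name] = drawn
    return pd.DataFrame(table)


def orr_curve(volumes: np.ndarray, V0: float, threshold: float,
              mode: str = "instantaneous") -> tuple[np.ndarray, float]:
    """ORR(t) and its time average from per-subject volume curves.

    ``instantaneous``: a subject responds at t iff V(t) <= threshold*V0;
    ``cumulative``: iff min over [0, t] of V <= threshold*V0 (RECIST
    best-response style, non-decreasing in t).
    """
    if mode == "cumulative":
        v = np.minimum.accumulate(volumes, axis=0)
    elif mode == "instantaneous":
        v = volumes
    else:
        raise ValueError(f"unknown mode {mode!r}")
    resp = v <= threshold * V0
    orr = resp.mean(axis=1)
    return orr, float(orr.mean())


def run_population(spec: PopulationSpec, params: ModelParams,
                   regimens: dict[str, Regimen] | None = None,
                   orr_mode: str = "instantaneous",
                   grid_step_h: float = 24.0,
                   steps_per_hour: int = 16) -> PopulationResult:
    """Monte Carlo virtual-population trial.

    Default regimens repeat the weekly cycle (PEM t.i.d. days 1-2, OSI
    daily) for the whole horizon under the sequential-48h and
    concurrent strategies.
    """
    horizon_h = spec.horizon_days * 24.0
    if regimens is None:
        n_cycles = int(math.ceil(spec.horizon_days / 7.0))
        regimens = {
            "sequential_48h": build_regimen("sequential", interval_h=48.0,
                                            n_cycles=n_cycles),
            "concurrent": build_regimen("concurrent", n_cycles=n_cycles),
        }
    cohort = draw_cohort(spec, params)
    overrides = {name: cohort[name].to_numpy() for name in IIV_PARAMETERS}
    P = pack_population(params, overrides)
    grid = np.arange(0.0, horizon_h + 1e-9, grid_step_h)
    V0 = params.tgi.V0

    volume_curves: dict[str, np.ndarray] = {}
    responder: dict[str, np.ndarray] = {}
    averaged: dict[str, float] = {}
    bands: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    for label, reg in regimens.items():
        ev = [e for e in reg.events if e.time <= horizon_h]
        reg_h = Regimen(events=tuple(ev), strategy_label=reg.strategy_label,
                        interval_h=reg.interval_h, n_cycles=reg.n_cycles,
                        cycle_length_days=reg.cycle_length_days)
        states = simulate_batch(reg_h, P, V0, grid,
                                steps_per_hour=steps_per_hour)
        vols = states[:, :, 9:13].sum(axis=2)       # (n_t, n)
        ok = np.all(np.isfinite(vols), axis=0)
        excluded[label] = int(np.sum(~ok))
        vols_ok = vols[:, ok]
        volume_curves[label] = vols_ok
        orr, avg = orr_curve(vols_ok, V0, spec.response_threshold,
                             mode=orr_mode)
        responder[label] = orr
        averaged[label] = avg
        bands[label] = np.percentile(vols_ok, [5, 50, 95], axis=1)
    return PopulationResult(spec=spec, times=grid, subject_params=cohort,
                            volume_curves=volume_curves,
                            responder_curves=responder,
                            time_averaged_orr=averaged,
                            percentile_bands=bands, excluded=excluded)
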
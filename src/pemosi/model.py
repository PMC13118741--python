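"""Trajectory simulation and derived pharmacodynamic metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .engine import IDX, STATE_NAMES
from .params import ModelParams, pack
from .regimen import Regimen

log = logging.getLogger(__name__)


def plasma_concentrations(state: np.ndarray, params: ModelParams
                          ) -> tuple[np.ndarray, np.ndarray]:
    """(Cpem in mg/L, Cosi in ug/L) from a state vector or state batch.

    Cpem = Xpem_1/V1; Cosi = Xosi_1/(V1/Fa) scaled from mg/L to ug/L.
    """
    arr = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = [STATE_NAMES[i] for i in
               np.unique(np.nonzero(~np.isfinite(np.atleast_2d(arr)))[-1])]
        raise ValueError(f"non-finite state component(s): {bad}")
    xp1 = arr[..., IDX["Xpem_1"]]
    xo1 = arr[..., IDX["Xosi_1"]]
    cpem = xp1 / params.pem.V1_pem
    cosi = xo1 / (params.osi.V1_osi / params.osi.Fa_osi) * 1000.0
    return cpem, cosi


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed system state plus derived series."""

    times: np.ndarray            # h, strictly increasing
    states: np.ndarray           # (n_t, 14)
    params: ModelParams
    regimen: Regimen

    @property
    def volume(self) -> np.ndarray:
        s = self.states
        return (s[:, IDX["X1"]] + s[:, IDX["X2"]]
                + s[:, IDX["X3"]] + s[:, IDX["X4"]])

    @property
    def cum_dead(self) -> np.ndarray:
        return self.states[:, IDX["CumDead"]]

    @property
    def damaged_fraction(self) -> np.ndarray:
        s = self.states
        dam = s[:, IDX["X2"]] + s[:, IDX["X3"]] + s[:, IDX["X4"]]
        return dam / np.maximum(self.volume, 1e-300)

    @property
    def x1_fraction(self) -> np.ndarray:
        return self.states[:, IDX["X1"]] / np.maximum(self.volume, 1e-300)

    def concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        return plasma_concentrations(self.states, self.params)

    def to_frame(self) -> pd.DataFrame:
        cpem, cosi = self.concentrations()
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.times)
        df["Cpem_mg_L"] = cpem
        df["Cosi_ug_L"] = cosi
        df["X_total"] = self.volume
        df["DamagedPct"] = self.damaged_fraction * 100.0
        df["X1Pct"] = self.x1_fraction * 100.0
        return df


def _check_grid(regimen: Regimen, t_end: float, output_grid) -> np.ndarray:
    if output_grid is None:
        grid = np.arange(0.0, t_end + 1e-9, 1.0)
    else:
        grid = np.asarray(output_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("output grid must be strictly increasing")
    late = [e.time for e in regimen.events if e.time > t_end]
    if late:
        raise ValueError(f"dose events beyond t_end={t_end}: {late}")
    return grid


def simulate(regimen: Regimen, params: ModelParams,
             t_end: float | None = None,
             output_grid=None,
             engine_name: str = "lsoda",
             steps_per_hour: int = 16) -> Trajectory:
    """Integrate the full system under a dosing regimen.

    ``engine_name`` selects ``"lsoda"`` (adaptive, stiff-capable,
    default) or ``"rk4"`` (the fixed-step batch engine run with a
    single subject; bit-identical to the population path).
    """
    if t_end is None:
        t_end = regimen.end_time
    grid = _check_grid(regimen, t_end, output_grid)
    P = pack(params)
    y0 = engine.initial_state(params.tgi.V0, n=1)
    ev = [(e.time, e.drug, e.amount) for e in regimen.events]
    if engine_name == "lsoda":
        states = engine.integrate_lsoda(y0[0], P, ev, grid)
    elif engine_name == "rk4":
        states = engine.integrate_rk4(y0, P, ev, grid,
                                      steps_per_hour=steps_per_hour)[:, 0, :]
    else:
        raise ValueError(f"unknown engine {engine_name!r}")
    neg = states.min()
    if neg < -1e-6 * max(params.tgi.V0, 1.0):
        log.warning("negative state components down to %.3g were produced "
                    "by the solver", neg)
    return Trajectory(times=grid, states=states, params=params,
                      regimen=regimen)


def simulate_batch(regimen: Regimen, P: np.ndarray, V0, grid: np.ndarray,
                   steps_per_hour: int = 16) -> np.ndarray:
    """Batch RK4 integration with per-subject packed parameters.

    ``P`` has shape (N_PACK,) or (N_PACK, n); ``V0`` is scalar or (n,).
    Returns states of shape (len(grid), n, 14).
    """
    n = 1 if P.ndim == 1 else P.shape[1]
    Y0 = engine.initial_state(1.0, n=n)
    Y0[:, IDX["X1"]] = V0
    ev = [(e.time, e.drug, e.amount) for e in regimen.events]
    return engine.integrate_rk4(Y0, P, ev, grid,
                                steps_per_hour=steps_per_hour)


def derived_metrics(traj: Trajectory, control_traj: Trajectory
                    ) -> pd.DataFrame:
    """Damaged%, X1%, TotalDead and TGI% versus a paired control.

    TGI%(t) = (1 - X_treated(t)/X_control(t)) * 100, the tumor growth
    inhibition of the treated arm relative to the unperturbed arm on a
    shared time grid.
    """
    if (len(traj.times) != len(control_traj.times)
            or not np.allclose(traj.times, control_traj.times)):
        raise ValueError("treated and control trajectories must share "
                         "a time grid")
    return pd.DataFrame({
        "time_h": traj.times,
        "DamagedPct": traj.damaged_fraction * 100.0,
        "X1Pct": traj.x1_fraction * 100.0,
        "TotalDead": traj.cum_dead,
        "TGIPct": (1.0 - traj.volume
                   / np.maximum(control_traj.volume, 1e-300)) * 100.0,
    })
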
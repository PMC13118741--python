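"""ODE right-hand side and integrators for the coupled PK-PD system.

State vector (one row per subject):

====  ==========  ==============================================
idx   name        meaning
====  ==========  ==============================================
0     Xpem_a      PEM amount in the i.p. depot, mg/kg
1     Xpem_1      PEM amount in the central compartment, mg/kg
2     Xpem_2      PEM amount in the peripheral compartment, mg/kg
3     Xosi_a      OSI amount in the gut depot, mg/kg
4     Xosi_1      OSI amount in the central compartment, mg/kg
5     Xosi_2      OSI amount in the peripheral compartment, mg/kg
6     Enzyme      normalised folate-metabolising enzyme level
7     Folate      normalised folate level
8     EGFR        normalised EGFR signal level
9     X1          proliferating tumor volume, mm^3
10    X2..X4      damaged-cell transit compartments, mm^3
13    CumDead     cumulative killed volume, mm^3
====  ==========  ==============================================

The X1->X2 flux is computed by one shared expression (mass conservation
by construction).  Hill drivers clip their arguments at zero so that
solver under/overshoot cannot produce negative concentrations, folate
deficits or EGFR deficits; raw states are left untouched.

Two integrators are provided:

* :func:`integrate_lsoda` - scipy LSODA (stiff/non-stiff switching BDF
  family), rtol 1e-6 / atol 1e-9, hard restart at every dose event;
  used for single trajectories.
* :func:`integrate_rk4` - fixed-step classical RK4 vectorised across an
  arbitrary batch of subjects (shared dosing schedule, per-subject
  parameters); used for Monte Carlo populations and Sobol sampling
  where thousands of parameter sets are integrated at once.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import params as P_

N_STATE = 14
IDX = {name: i for i, name in enumerate(
    ("Xpem_a", "Xpem_1", "Xpem_2", "Xosi_a", "Xosi_1", "Xosi_2",
     "Enzyme", "Folate", "EGFR", "X1", "X2", "X3", "X4", "CumDead"))}
STATE_NAMES = tuple(IDX)

_EPS = 1e-300


def initial_state(V0: float, n: int = 1) -> np.ndarray:
    """Drug-free homeostatic initial condition with tumor volume ``V0``."""
    Y = np.zeros((n, N_STATE))
    Y[:, IDX["Enzyme"]] = 1.0
    Y[:, IDX["Folate"]] = 1.0
    Y[:, IDX["EGFR"]] = 1.0
    Y[:, IDX["X1"]] = V0
    return Y


def transition_flux(X1, folate, egfr, k1, Emax_f, EC50_f, g_fol, g_G1):
    """Drug-amplified X1->X2 flux (the single shared expression).

    ``k1*X1*(1 + Emax_f*D^g/(EC50_f^g + D^g))*EGFR^g_G1`` with the
    folate deficit ``D = max(0, 1 - Folate)``; EGFR above baseline
    (feedback rebound) accelerates the transition, EGFR below baseline
    (G1 arrest under OSI) gates it down.
    """
    D = np.maximum(0.0, 1.0 - folate)
    Dg = D ** g_fol
    hill = Emax_f * Dg / (EC50_f ** g_fol + Dg + _EPS)
    return k1 * X1 * (1.0 + hill) * np.maximum(egfr, 0.0) ** g_G1


def rhs(t: float, Y: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Vectorised system derivative.

    Parameters
    ----------
    Y : (n, 14) state batch.
    P : packed parameter vector, shape (35,) or (35, n).
    """
    dY = np.empty_like(Y)
    (ka_p, V1_p, k12_p, k21_p, kel_p, _F_p,
     ka_o, Fa_o, V1F_o, k12_o, k21_o, kel_o,
     ko_enz, ko_fol, Emax_pem, EC50_pem, g_enz,
     ko_eg, Imax_o, EC50_o, g_osi, k_fb, g_fb,
     lam0, lam1, psi, k1, k2,
     Emax_f, EC50_f, g_fol, g_EGFR, g_G1, k_bim, g_bim) = P

    Xpa, Xp1, Xp2 = Y[:, 0], Y[:, 1], Y[:, 2]
    Xoa, Xo1, Xo2 = Y[:, 3], Y[:, 4], Y[:, 5]
    enz, fol, egfr = Y[:, 6], Y[:, 7], Y[:, 8]
    X1, X2, X3, X4 = Y[:, 9], Y[:, 10], Y[:, 11], Y[:, 12]

    # --- PK ---------------------------------------------------------
    dY[:, 0] = -ka_p * Xpa
    dY[:, 1] = ka_p * Xpa - (k12_p + kel_p) * Xp1 + k21_p * Xp2
    dY[:, 2] = k12_p * Xp1 - k21_p * Xp2
    abs_o = Fa_o * ka_o * Xoa
    dY[:, 3] = -abs_o
    dY[:, 4] = abs_o - (k12_o + kel_o) * Xo1 + k21_o * Xo2
    dY[:, 5] = k12_o * Xo1 - k21_o * Xo2

    Cpem = np.maximum(Xp1, 0.0) / V1_p                    # mg/L
    Cosi = np.maximum(Xo1, 0.0) / V1F_o * 1000.0          # ug/L

    # --- folate cascade --------------------------------------------
    stim = Emax_pem * Cpem / (EC50_pem + Cpem)
    dY[:, 6] = ko_enz - ko_enz * enz * (1.0 + stim)
    dY[:, 7] = np.maximum(enz, 0.0) ** g_enz * ko_fol - ko_fol * fol

    # --- EGFR signal -------------------------------------------------
    X = X1 + X2 + X3 + X4
    damaged = (X2 + X3 + X4) / (X + _EPS)                 # fraction in [0,1]
    Cg = Cosi ** g_osi
    inact = Imax_o * Cg / (EC50_o ** g_osi + Cg + _EPS)
    dY[:, 8] = (ko_eg * (1.0 + k_fb * damaged ** g_fb)
                - ko_eg * egfr * (1.0 + inact))

    # --- tumor -------------------------------------------------------
    egfr_pos = np.maximum(egfr, 0.0)
    growth = (lam0 * X1 * egfr_pos ** g_EGFR
              / (1.0 + (lam0 / lam1 * X) ** psi) ** (1.0 / psi))
    flux12 = transition_flux(X1, fol, egfr_pos, k1, Emax_f, EC50_f,
                             g_fol, g_G1)
    bim = 1.0 + k_bim * np.maximum(0.0, 1.0 - egfr) ** g_bim
    k2b = k2 * bim
    dY[:, 9] = growth - flux12
    dY[:, 10] = flux12 - k2b * X2
    dY[:, 11] = k2b * (X2 - X3)
    dY[:, 12] = k2b * (X3 - X4)
    dY[:, 13] = k2b * X4
    return dY


# ----------------------------------------------------------------------
# Event handling shared by both integrators
# ----------------------------------------------------------------------

def _event_table(events: Sequence[tuple[float, str, float]]):
    """Convert (time, drug, amount) triples to (time, state index, add)."""
    out = []
    for time, drug, amount in events:
        if drug == "PEM":
            out.append((float(time), IDX["Xpem_a"], float(amount)))
        elif drug == "OSI":
            out.append((float(time), IDX["Xosi_a"], float(amount)))
        else:
            raise ValueError(f"unknown drug {drug!r}")
    return sorted(out, key=lambda e: e[0])


def _breakpoints(event_times, grid):
    pts = np.unique(np.concatenate([np.asarray(event_times, dtype=float),
                                    np.asarray(grid, dtype=float)]))
    return pts


def apply_doses(Y: np.ndarray, table, time: float, F_pem: float) -> None:
    for t_ev, idx, amount in table:
        if t_ev == time:
            add = amount * F_pem if idx == IDX["Xpem_a"] else amount
            Y[:, idx] += add


def integrate_rk4(Y0: np.ndarray, P: np.ndarray,
                  events: Sequence[tuple[float, str, float]],
                  grid: np.ndarray,
                  steps_per_hour: int = 16) -> np.ndarray:
    """Fixed-step RK4 over a batch; returns (len(grid), n, 14).

    Doses are applied as jumps in the depot compartments exactly at
    their event times (events and grid points are both integration
    breakpoints).  The step is 1/steps_per_hour h within each segment,
    short segments are subdivided at least once.
    """
    grid = np.asarray(grid, dtype=float)
    table = _event_table(events)
    F_pem = np.atleast_1d(P[P_.PACK_INDEX["F_pem"]])[0]
    pts = _breakpoints([e[0] for e in table], grid)
    if pts[0] > 0.0:
        pts = np.concatenate([[0.0], pts])
    grid_set = {round(g, 9) for g in grid}
    out = np.empty((len(grid), Y0.shape[0], N_STATE))
    Y = Y0.copy()
    k_out = 0
    apply_doses(Y, table, pts[0], F_pem)
    if round(pts[0], 9) in grid_set:
        out[k_out] = Y
        k_out += 1
    for a, b in zip(pts[:-1], pts[1:]):
        n_sub = max(1, int(np.ceil((b - a) * steps_per_hour - 1e-9)))
        h = (b - a) / n_sub
        t = a
        for _ in range(n_sub):
            k1 = rhs(t, Y, P)
            k2 = rhs(t + h / 2, Y + h / 2 * k1, P)
            k3 = rhs(t + h / 2, Y + h / 2 * k2, P)
            k4 = rhs(t + h, Y + h * k3, P)
            Y = Y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        apply_doses(Y, table, b, F_pem)
        if round(b, 9) in grid_set:
            out[k_out] = Y
            k_out += 1
    if k_out != len(grid):
        raise RuntimeError("output grid not fully covered by breakpoints")
    return out


class SolverFailure(RuntimeError):
    def __init__(self, time: float, state: np.ndarray, message: str):
        self.time = time
        self.state = state
        super().__init__(f"ODE solver failed at t={time:.4g} h: {message}; "
                         f"state={np.array2string(state, precision=4)}")


def integrate_lsoda(y0: np.ndarray, P: np.ndarray,
                    events: Sequence[tuple[float, str, float]],
                    grid: np.ndarray,
                    rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
    """Stiff-capable single-subject integration; returns (len(grid), 14)."""
    grid = np.asarray(grid, dtype=float)
    table = _event_table(events)
    F_pem = P[P_.PACK_INDEX["F_pem"]]
    pts = _breakpoints([e[0] for e in table], grid)
    if pts[0] > 0.0:
        pts = np.concatenate([[0.0], pts])
    grid_set = {round(g, 9) for g in grid}
    out = np.empty((len(grid), N_STATE))
    Y = y0.copy().reshape(1, N_STATE)
    k_out = 0

    def f(t, y):
        return rhs(t, y.reshape(1, N_STATE), P).ravel()

    apply_doses(Y, table, pts[0], F_pem)
    if round(pts[0], 9) in grid_set:
        out[k_out] = Y[0]
        k_out += 1
    for a, b in zip(pts[:-1], pts[1:]):
        sol = solve_ivp(f, (a, b), Y[0], method="LSODA",
                        rtol=rtol, atol=atol, dense_output=False,
                        t_eval=[b])
        if not sol.success:
            raise SolverFailure(a, Y[0], sol.message)
        Y = sol.y[:, -1].reshape(1, N_STATE)
        apply_doses(Y, table, b, F_pem)
        if round(b, 9) in grid_set:
            out[k_out] = Y[0]
            k_out += 1
    if k_out != len(grid):
        raise RuntimeError("output grid not fully covered by breakpoints")
    return out
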
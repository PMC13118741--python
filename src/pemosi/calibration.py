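"""Stepwise parameter estimation from time-series data.

Each fitter estimates one small block of the model from the experiment
that isolates it (stepwise calibration): two-compartment PK from
plasma profiles, EGFR turnover from signal-recovery curves, potencies
from 4PL dose-response tables, the EGFR-proliferation exponent and the
folate-cytotoxicity block from in vitro TGI%-time curves, the
apoptosis exponent from power-law signal pairs, and the Simeoni growth
constants from control tumor volumes.  Later steps consume earlier
estimates as fixed values.

All nonlinear fits use bounded least squares with five log-spaced
multi-starts; PK profiles are fitted on the log-concentration scale,
TGI% curves with unit weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import least_squares


@dataclass(frozen=True)
class TimeSeries:
    times: np.ndarray            # h
    values: np.ndarray
    sd: np.ndarray | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be non-decreasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))


@dataclass
class FitResult:
    estimates: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    objective: float = np.nan
    converged: bool = False
    n_iter: int = 0
    message: str = ""

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


@dataclass(frozen=True)
class NCAResult:
    Cmax: float
    Tmax: float
    AUClast: float
    AUCinf: float
    t_half: float
    lambda_z: float


# ----------------------------------------------------------------------
# generic bounded multi-start least squares
# ----------------------------------------------------------------------

def _multistart(residual_fn, x0, bounds, n_starts: int = 5):
    """Bounded least squares from log-spaced multiplicative starts."""
    x0 = np.asarray(x0, dtype=float)
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    best = None
    total_nfev = 0
    for mult in np.geomspace(0.2, 5.0, n_starts):
        start = np.clip(x0 * mult, lo * 1.000001 + 1e-12, hi * 0.999999)
        try:
            sol = least_squares(residual_fn, start, bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    best.nfev_total = total_nfev
    return best


def _standard_errors(sol, names):
    """Gauss-Newton SEs from the residual Jacobian (NaN if singular)."""
    m, k = sol.jac.shape
    dof = max(m - k, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return dict(zip(names, se))


def _result(sol, names, converged=None, message=""):
    est = dict(zip(names, sol.x))
    return FitResult(estimates=est, se=_standard_errors(sol, names),
                     objective=2.0 * sol.cost,
                     converged=bool(sol.success) if converged is None
                     else converged,
                     n_iter=getattr(sol, "nfev_total", sol.nfev),
                     message=message)


# ----------------------------------------------------------------------
# EGFR recovery after washout: EGFR(t) = 1 - exp(-kout t), EGFR(0) = 0
# ----------------------------------------------------------------------

def fit_egfr_recovery(data: TimeSeries) -> FitResult:
    """Estimate the EGFR turnover rate (1/day) from a recovery curve.

    The signal is normalised to baseline 1 and fully depleted at t=0,
    so the turnover ODE integrates to ``1 - exp(-kout*t)``.
    """
    t_day = data.times / 24.0
    y = data.values
    if np.allclose(y, 0.0):
        return FitResult(estimates={"kout_EGFR": np.nan}, converged=False,
                         message="all-zero recovery data: kout not "
                                 "identifiable")

    def resid(x):
        return (1.0 - np.exp(-x[0] * t_day)) - y

    sol = _multistart(resid, [1.0], ([1e-6], [1e3]))
    return _result(sol, ["kout_EGFR"])


# ----------------------------------------------------------------------
# four-parameter logistic dose-response
# ----------------------------------------------------------------------

def four_pl(conc, bottom, top, ec50, hill):
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / np.maximum(conc, 1e-300))
                                      ** hill)


def fit_4pl(conc, response) -> FitResult:
    """Fit bottom/top/EC50/hill; EC50 is reported in the input units."""
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(response, dtype=float)
    if len(np.unique(conc[conc > 0])) < 5:
        raise ValueError("need >= 5 concentration levels")
    span = resp.max() - resp.min()
    if span < 1e-12 * max(1.0, abs(resp.max())):
        return FitResult(estimates={"bottom": resp.mean(), "top": resp.mean(),
                                    "EC50": np.nan, "hill": np.nan},
                         converged=False,
                         message="constant response: EC50 not identifiable")

    def resid(x):
        bottom, top, lec50, hill = x
        return four_pl(conc, bottom, top, 10.0 ** lec50, hill) - resp

    c_pos = conc[conc > 0]
    x0 = [resp.min(), resp.max(), np.log10(np.median(c_pos)), 1.0]
    lo = [resp.min() - 2 * span - 1.0, resp.min() - 2 * span - 1.0,
          np.log10(c_pos.min()) - 3, 0.05]
    hi = [resp.max() + 2 * span + 1.0, resp.max() + 2 * span + 1.0,
          np.log10(c_pos.max()) + 3, 10.0]
    sol = _multistart(lambda x: resid(x), x0, (lo, hi))
    est = {"bottom": sol.x[0], "top": sol.x[1], "EC50": 10.0 ** sol.x[2],
           "hill": sol.x[3]}
    res = _result(sol, ["bottom", "top", "logEC50", "hill"])
    res.estimates = est
    res.se["EC50"] = res.se.pop("logEC50", np.nan) * est["EC50"] * np.log(10)
    if not monotone_within_noise(conc, resp):
        res.message = (res.message + "; non-monotone dose-response beyond "
                       "noise").lstrip("; ")
    return res


def monotone_within_noise(conc, resp, tol_frac: float = 0.25) -> bool:
    order = np.argsort(conc)
    r = np.asarray(resp, dtype=float)[order]
    span = max(r.max() - r.min(), 1e-12)
    inc = np.all(np.diff(r) >= -tol_frac * span)
    dec = np.all(np.diff(r) <= tol_frac * span)
    return bool(inc or dec)


# ----------------------------------------------------------------------
# gamma_EGFR from an in vitro TGI% curve under constant OSI exposure
# ----------------------------------------------------------------------

def gamma_egfr_model(times_h, gamma, egfr_level, kng):
    """Numerically integrated treated/control pair -> TGI%(t).

    dX1/dt = kng*X1*EGFR^gamma (treated), dX2/dt = kng*X2 (control),
    TGI% = (1 - X1/X2)*100.
    """
    def f(t, y):
        return [kng * y[0] * egfr_level ** gamma, kng * y[1]]

    sol = solve_ivp(f, (0.0, float(times_h[-1])), [1.0, 1.0],
                    t_eval=times_h, rtol=1e-10, atol=1e-12)
    return (1.0 - sol.y[0] / sol.y[1]) * 100.0


def fit_gamma_egfr(tgi: TimeSeries, egfr_level: float, kng: float
                   ) -> FitResult:
    """Estimate gamma_EGFR from a TGI%-time curve at a fixed EGFR level.

    ``egfr_level`` is the measured fraction-of-baseline EGFR under the
    constant exposure; ``kng`` is the in vitro growth rate in 1/h.
    """
    if not (0 < egfr_level < 1):
        if egfr_level == 1:
            return FitResult(estimates={"gamma_EGFR": np.nan},
                             converged=False,
                             message="EGFR at baseline: gamma not "
                                     "identifiable")
        raise ValueError("egfr_level must be in (0, 1)")
    if kng <= 0:
        raise ValueError("kng must be > 0")
    t = tgi.times

    def resid(x):
        return gamma_egfr_model(t, x[0], egfr_level, kng) - tgi.values

    sol = _multistart(resid, [0.5], ([1e-4], [20.0]))
    return _result(sol, ["gamma_EGFR"])


# ----------------------------------------------------------------------
# folate cytotoxicity block from an in vitro TGI% curve under constant PEM
# ----------------------------------------------------------------------

def folate_mini_model(times_h, pem_conc, p, drop_control_loss=False):
    """Five-compartment in vitro mini-model; returns TGI%(t).

    Treated cells X1..X4 experience the folate-deficit-driven
    X1->X2 transition with downstream k2 transit; the control
    population X5 grows exponentially (with the printed baseline -k1
    loss unless ``drop_control_loss``).  The enzyme/folate cascade runs
    under the constant PEM concentration ``pem_conc`` (mg/L).
    """
    kng = p["kng"]
    k1, k2 = p["k1"], p["k2"]
    ko_e, ko_f = p["kout_enzyme"], p["kout_folate"]
    ec50_pem, ec50_f = p["EC50_pem"], p["EC50_folate"]
    emax_pem, g_enz, emax_f = p["Emax_pem"], p["gamma_enzyme"], p["Emax_folate"]
    g_fol = p.get("gamma_folate", 1.0)
    stim = emax_pem * pem_conc / (ec50_pem + pem_conc)
    k5 = 0.0 if drop_control_loss else k1

    def f(t, y):
        X1, X2, X3, X4, X5, enz, fol = y
        D = max(0.0, 1.0 - fol)
        Dg = D ** g_fol
        kill = k1 * X1 * (1.0 + emax_f * Dg / (ec50_f ** g_fol + Dg + 1e-300))
        return [kng * X1 - kill,
                kill - k2 * X2,
                k2 * (X2 - X3),
                k2 * (X3 - X4),
                kng * X5 - k5 * X5,
                ko_e - ko_e * enz * (1.0 + stim),
                max(0.0, enz) ** g_enz * ko_f - ko_f * fol]

    sol = solve_ivp(f, (0.0, float(times_h[-1])), [1, 0, 0, 0, 1, 1, 1],
                    t_eval=times_h, rtol=1e-9, atol=1e-11, method="LSODA")
    treated = sol.y[0] + sol.y[1] + sol.y[2] + sol.y[3]
    return (1.0 - treated / sol.y[4]) * 100.0


def fit_folate_cytotoxicity(tgi: TimeSeries, pem_conc: float,
                            fixed: dict[str, float],
                            drop_control_loss: bool = False,
                            free: tuple[str, ...] = ("Emax_pem",
                                                     "gamma_enzyme",
                                                     "Emax_folate"),
                            ) -> FitResult:
    """Estimate (Emax_pem, gamma_enzyme, Emax_folate) from TGI% data.

    ``fixed`` must supply kng (1/h), kout_enzyme, kout_folate (1/h),
    EC50_pem (mg/L), EC50_folate, k1 and k2 (1/h); ``free`` can be
    narrowed when a parameter is fixed by design.
    """
    needed = {"kng", "kout_enzyme", "kout_folate", "EC50_pem",
              "EC50_folate", "k1", "k2"}
    missing = needed - set(fixed)
    if missing:
        raise ValueError(f"missing fixed parameters: {sorted(missing)}")
    if len(tgi.times) < len(free):
        raise ValueError("fewer time points than free parameters")
    t = tgi.times
    x0_all = {"Emax_pem": 5.0, "gamma_enzyme": 1.0, "Emax_folate": 10.0}
    lo_all = {"Emax_pem": 1e-3, "gamma_enzyme": 0.05, "Emax_folate": 1e-3}
    hi_all = {"Emax_pem": 1e3, "gamma_enzyme": 10.0, "Emax_folate": 1e4}

    def resid(x):
        p = dict(fixed)
        p.update(dict(zip(free, x)))
        return folate_mini_model(t, pem_conc, p,
                                 drop_control_loss=drop_control_loss) \
            - tgi.values

    sol = _multistart(resid, [x0_all[n] for n in free],
                      ([lo_all[n] for n in free], [hi_all[n] for n in free]))
    return _result(sol, list(free))


def folate_steady_state(pem_conc: float, Emax_pem: float, EC50_pem: float,
                        gamma_enzyme: float) -> tuple[float, float]:
    """Algebraic steady state (Enzyme_ss, Folate_ss) under constant PEM."""
    enz = 1.0 / (1.0 + Emax_pem * pem_conc / (EC50_pem + pem_conc))
    return enz, enz ** gamma_enzyme


# ----------------------------------------------------------------------
# gamma_bim from power-law apoptosis signal
# ----------------------------------------------------------------------

def fit_gamma_bim(egfr_deficit, clparp) -> FitResult:
    """Fit ``clparp = a * (1-EGFR)^gamma_bim`` by log-log regression."""
    x = np.asarray(egfr_deficit, dtype=float)
    y = np.asarray(clparp, dtype=float)
    ok = (x > 0) & (y > 0)
    if not np.all(ok):
        warnings.warn(f"excluding {np.sum(~ok)} non-positive point(s) from "
                      "log-log fit")
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return FitResult(estimates={"gamma_bim": np.nan, "gain": np.nan},
                         converged=False, message="too few positive points")
    reg = stats.linregress(np.log(x), np.log(y))
    return FitResult(
        estimates={"gamma_bim": reg.slope, "gain": float(np.exp(reg.intercept))},
        se={"gamma_bim": reg.stderr if reg.stderr is not None else np.nan},
        objective=float(np.sum((np.log(y) - reg.intercept
                                - reg.slope * np.log(x)) ** 2)),
        converged=True)


# ----------------------------------------------------------------------
# Simeoni growth constants from control tumor volumes
# ----------------------------------------------------------------------

def simeoni_control_model(times_h, lambda0_day, lambda1_day, V0,
                          k1_day=0.0, k2_day=0.0, psi=20.0):
    """Unperturbed tumor volume (mm^3) on ``times_h``.

    Exponential-to-linear Simeoni growth of X1 with the baseline
    k1/k2 damage cycle running at its drug-free rates.
    """
    lam0, lam1 = lambda0_day / 24.0, lambda1_day / 24.0
    k1, k2 = k1_day / 24.0, k2_day / 24.0

    def f(t, y):
        X1, X2, X3, X4 = y
        X = X1 + X2 + X3 + X4
        growth = lam0 * X1 / (1.0 + (lam0 / lam1 * X) ** psi) ** (1.0 / psi)
        return [growth - k1 * X1,
                k1 * X1 - k2 * X2,
                k2 * (X2 - X3),
                k2 * (X3 - X4)]

    sol = solve_ivp(f, (0.0, float(times_h[-1])), [V0, 0, 0, 0],
                    t_eval=times_h, rtol=1e-9, atol=1e-9, method="LSODA")
    return sol.y.sum(axis=0)


def fit_simeoni_control(volumes: TimeSeries, V0: float,
                        k1_day: float = 0.0, k2_day: float = 0.0,
                        psi: float = 20.0) -> FitResult:
    """Estimate (lambda0 1/day, lambda1 mm^3/day) from control volumes."""
    if len(volumes.times) < 5:
        raise ValueError("need >= 5 control time points")
    t = volumes.times

    def resid(x):
        return simeoni_control_model(t, x[0], x[1], V0, k1_day, k2_day,
                                     psi) - volumes.values

    sol = _multistart(resid, [0.1, 50.0], ([1e-4, 1e-2], [10.0, 1e4]))
    return _result(sol, ["lambda0", "lambda1"])


# ----------------------------------------------------------------------
# two-compartment PK
# ----------------------------------------------------------------------

def two_compartment_profile(times_h, dose, ka, V1, k12, k21, kel,
                            route="ip", F=1.0):
    """Exact concentration profile via the matrix exponential.

    For ``iv`` the dose is a central-compartment bolus; for ``ip`` and
    ``oral`` it enters a first-order depot (F fixed 1 for i.p.).  The
    returned concentration is dose*F-scaled amount over V1 (an apparent
    V1/F for oral data).
    """
    times_h = np.asarray(times_h, dtype=float)
    if route == "iv":
        A = np.array([[-(k12 + kel), k21], [k12, -k21]])
        y0 = np.array([dose, 0.0])
        sel = 0
    else:
        A = np.array([[-ka, 0.0, 0.0],
                      [F * ka, -(k12 + kel), k21],
                      [0.0, k12, -k21]])
        y0 = np.array([dose, 0.0, 0.0])
        sel = 1
    # eigen-decomposition once, propagate to all sample times
    w, V = np.linalg.eig(A)
    c = np.linalg.solve(V, y0)
    amounts = (V[sel] * c) @ np.exp(np.outer(w, times_h))
    return np.real(amounts) / V1


def fit_two_compartment(conc: TimeSeries, dose: float, route: str = "ip"
                        ) -> FitResult:
    """Fit two-compartment PK on log-concentrations.

    Returns ka (absent for iv), V1, k12, k21, kel.  Bioavailability is
    fixed at 1 for i.p.; for oral data V1 is the apparent V1/F.
    """
    if route not in ("iv", "ip", "oral"):
        raise ValueError(f"unknown route {route!r}")
    if len(conc.times) < 6:
        raise ValueError("need >= 6 concentration points")
    y = conc.values
    if y.max() <= 0 or (y.max() - y.min()) < 1e-9 * y.max():
        return FitResult(estimates={}, converged=False,
                         message="flat profile: not identifiable")
    t = conc.times
    names = (["V1", "k12", "k21", "kel"] if route == "iv"
             else ["ka", "V1", "k12", "k21", "kel"])

    def resid(x):
        p = dict(zip(names, np.exp(x)))
        pred = two_compartment_profile(t, dose, p.get("ka", 0.0), p["V1"],
                                       p["k12"], p["k21"], p["kel"],
                                       route=route)
        return np.log(np.maximum(pred, 1e-12)) - np.log(np.maximum(y, 1e-12))

    x0 = np.log([1.0, dose / max(y.max(), 1e-9), 0.3, 0.8, 0.5])
    if route == "iv":
        x0 = x0[1:]
    lo = np.full(len(names), np.log(1e-5))
    hi = np.full(len(names), np.log(1e4))
    sol = _multistart(resid, x0, (lo, hi))
    est = dict(zip(names, np.exp(sol.x)))
    res = _result(sol, names)
    res.estimates = est
    res.se = {n: s * est[n] for n, s in res.se.items()}  # delta method
    return res


# ----------------------------------------------------------------------
# non-compartmental analysis
# ----------------------------------------------------------------------

def nca(conc: TimeSeries, dose: float | None = None) -> NCAResult:
    """Model-free exposure summary.

    AUClast by linear-up/log-down trapezoids; lambda_z by log-linear
    regression on the terminal points (the post-Tmax tail size with the
    best adjusted R^2, >= 3 points); AUCinf = AUClast + Clast/lambda_z.
    """
    t = conc.times
    y = conc.values
    if len(t) < 2:
        raise ValueError("need >= 2 points for NCA")
    i_max = int(np.argmax(y))
    cmax, tmax = float(y[i_max]), float(t[i_max])

    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = y[i], y[i + 1]
        if c2 < c1 and c2 > 0 and c1 > 0:
            auc += dt * (c1 - c2) / np.log(c1 / c2)     # log-down
        else:
            auc += dt * (c1 + c2) / 2.0                 # linear-up
    # terminal slope
    tail_mask = (np.arange(len(t)) > i_max) & (y > 0)
    idx = np.nonzero(tail_mask)[0]
    lambda_z = np.nan
    best_r2 = -np.inf
    for n_tail in range(3, len(idx) + 1):
        sub = idx[-n_tail:]
        reg = stats.linregress(t[sub], np.log(y[sub]))
        k = len(sub)
        r2adj = 1.0 - (1.0 - reg.rvalue ** 2) * (k - 1) / max(k - 2, 1)
        if reg.slope < 0 and r2adj > best_r2:
            best_r2 = r2adj
            lambda_z = -reg.slope
    if not np.isfinite(lambda_z):
        warnings.warn("non-positive terminal slope: AUCinf undefined")
        return NCAResult(cmax, tmax, auc, np.nan, np.nan, np.nan)
    clast = y[np.nonzero(y > 0)[0][-1]]
    return NCAResult(Cmax=cmax, Tmax=tmax, AUClast=auc,
                     AUCinf=auc + clast / lambda_z,
                     t_half=np.log(2.0) / lambda_z, lambda_z=lambda_z)


DDI_WINDOW = (0.8, 1.25)


def ddi_assessment(combo: NCAResult, mono: NCAResult) -> dict:
    """Exposure ratios (combo/mono) and the bioequivalence-window flag.

    'No meaningful DDI' iff every ratio lies in the closed interval
    [0.8, 1.25].
    """
    ratios = {}
    for name in ("Cmax", "AUClast", "AUCinf"):
        denom = getattr(mono, name)
        num = getattr(combo, name)
        if not np.isfinite(denom) or denom == 0:
            raise ZeroDivisionError(f"mono {name} is zero or undefined")
        if np.isfinite(num):
            ratios[name] = num / denom
    lo, hi = DDI_WINDOW
    no_ddi = all(lo <= r <= hi for r in ratios.values())
    return {"ratios": ratios, "no_meaningful_ddi": no_ddi}
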
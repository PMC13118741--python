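"""Variance-based global sensitivity analysis.

Saltelli's radial sampling scheme with Jansen estimators: for ``d``
factors and base sample size ``n`` the model is evaluated at the two
independent matrices A and B plus the d hybrid matrices AB_i (column i
of A replaced by B), a total of ``n*(d+2)`` runs.

    S_i  = 1 - E[(f(B) - f(AB_i))^2] / (2 Var)
    ST_i =     E[(f(A) - f(AB_i))^2] / (2 Var)

Sampling uses a scrambled Sobol' low-discrepancy sequence mapped to
independent uniform ranges; confidence intervals are bootstrap
percentiles over resampled rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc


@dataclass(frozen=True)
class SobolSpec:
    parameters: dict[str, float]            # name -> baseline value
    range_factors: dict[str, tuple[float, float]]  # name -> (low, high) mult
    n_samples: int = 1000
    output: str = "tgi_day18"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 64:
            raise ValueError("n_samples must be >= 64")
        for name, (lo, hi) in self.range_factors.items():
            if not lo < hi:
                raise ValueError(f"range for {name!r} must have low < high")

    @property
    def names(self) -> list[str]:
        return list(self.parameters)


@dataclass
class SobolResult:
    names: list[str]
    first_order: np.ndarray
    total_order: np.ndarray
    ci: dict[str, np.ndarray] = field(default_factory=dict)
    n_evaluations: int = 0
    n_failed: int = 0

    def ranking(self, order: str = "total") -> list[str]:
        values = self.total_order if order == "total" else self.first_order
        return [self.names[i] for i in np.argsort(values)[::-1]]


def saltelli_sample(bounds: np.ndarray, n: int, seed: int = 0
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B (n x d) and AB (d, n, d) matrices of uniform samples."""
    d = bounds.shape[0]
    eng = qmc.Sobol(2 * d, scramble=True, rng=np.random.default_rng(seed))
    U = eng.random(n)
    A = qmc.scale(U[:, :d], bounds[:, 0], bounds[:, 1])
    B = qmc.scale(U[:, d:], bounds[:, 0], bounds[:, 1])
    AB = np.repeat(A[None, :, :], d, axis=0)
    for i in range(d):
        AB[i, :, i] = B[:, i]
    return A, B, AB


def jansen_indices(fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """First- and total-order indices from model outputs.

    fA, fB: (n,); fAB: (d, n).
    """
    allf = np.concatenate([fA, fB])
    var = np.var(allf)
    if var <= 0:
        d = fAB.shape[0]
        return np.zeros(d), np.zeros(d)
    first = 1.0 - np.mean((fB[None, :] - fAB) ** 2, axis=1) / (2.0 * var)
    total = np.mean((fA[None, :] - fAB) ** 2, axis=1) / (2.0 * var)
    return first, total


def _bootstrap_ci(fA, fB, fAB, n_boot=200, alpha=0.05, seed=0):
    rng = np.random.default_rng(seed)
    n = len(fA)
    d = fAB.shape[0]
    firsts = np.empty((n_boot, d))
    totals = np.empty((n_boot, d))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        firsts[b], totals[b] = jansen_indices(fA[idx], fB[idx], fAB[:, idx])
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    return {"first_order": np.percentile(firsts, qs, axis=0).T,
            "total_order": np.percentile(totals, qs, axis=0).T}


def sobol_indices(func, bounds: np.ndarray, n: int, seed: int = 0,
                  n_boot: int = 200) -> SobolResult:
    """Estimate Sobol indices of a vectorised ``func(X) -> (m,)``.

    ``func`` receives an (m, d) matrix of parameter points and must
    return one output per row; rows where the model fails should come
    back NaN - failed rows are dropped pairwise and counted.
    """
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    A, B, AB = saltelli_sample(bounds, n, seed=seed)
    X = np.vstack([A, B, AB.reshape(d * n, d)])
    out = np.asarray(func(X), dtype=float)
    fA, fB = out[:n], out[n:2 * n]
    fAB = out[2 * n:].reshape(d, n)
    ok = np.isfinite(fA) & np.isfinite(fB) & np.all(np.isfinite(fAB), axis=0)
    n_failed = int(np.sum(~ok))
    fA, fB, fAB = fA[ok], fB[ok], fAB[:, ok]
    first, total = jansen_indices(fA, fB, fAB)
    ci = _bootstrap_ci(fA, fB, fAB, n_boot=n_boot, seed=seed)
    return SobolResult(names=[f"x{i}" for i in range(d)],
                       first_order=first, total_order=total, ci=ci,
                       n_evaluations=len(out), n_failed=n_failed)
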
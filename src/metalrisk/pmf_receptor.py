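"""Positive matrix factorization (PMF) receptor model.

The receptor model decomposes a samples-by-metals concentration matrix X
into non-negative factor contributions G (samples x factors) and factor
profiles F (factors x metals),

    X_iy ~= sum_a G_ia F_ay,

by minimising the uncertainty-weighted objective

    Q = sum_iy ( (X_iy - (G F)_iy) / alpha_iy )^2.

Per-cell uncertainties follow the standard detection-limit construction:
alpha = (5/6) * MDL where the raw value is at or below the MDL, and
alpha = 0.05 * X + MDL above it.

The solver is alternating multiplicative weighted non-negative least
squares with multi-start (default 20 random initialisations); the run with
the lowest robust objective wins. Robust mode down-weights outlier cells:
where the scaled residual r = e/alpha exceeds 4 in magnitude the cell's
effective uncertainty is inflated so its scaled residual becomes
sqrt(4*|r|), giving Q_robust = sum min(r^2, 4*|r|) <= Q_true.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_tables import Metal, SampleMatrix, ValidationError

__all__ = [
    "UncertaintyMatrix",
    "FactorSolution",
    "PmfConvergenceError",
    "build_uncertainty",
    "fit_pmf",
    "factor_contributions",
    "diagnostics",
]

ROBUST_CUTOFF = 4.0
_EPS = 1e-12


class PmfConvergenceError(RuntimeError):
    """No random start converged; carries per-run diagnostics."""

    def __init__(self, message: str, per_run: list[dict]):
        super().__init__(message)
        self.per_run = per_run


@dataclass(frozen=True)
class UncertaintyMatrix:
    alpha: np.ndarray  # same shape as the data, mg/kg, all > 0
    metals: tuple[Metal, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, float)
        if np.any(~np.isfinite(a)) or np.any(a <= 0):
            raise ValidationError("uncertainties must be finite and positive")


@dataclass
class FactorSolution:
    g: np.ndarray  # (n_samples, n_factors) >= 0
    f: np.ndarray  # (n_factors, n_metals) >= 0
    q_true: float
    q_robust: float
    n_factors: int
    metals: tuple[Metal, ...]
    seed_of_best: int
    n_converged: int
    q_history: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    @property
    def predicted(self) -> np.ndarray:
        return self.g @ self.f

    @property
    def contributions_pct(self) -> pd.DataFrame:
        return factor_contributions(self)


def build_uncertainty(matrix: SampleMatrix) -> UncertaintyMatrix:
    """Per-cell uncertainties from the MDL rules.

    The at-or-below-MDL branch tests the raw (pre-substitution) value.
    """
    if matrix.mdl is None:
        raise ValidationError("sample matrix has no MDL configured")
    missing = [m.value for m in matrix.metals if m not in matrix.mdl]
    if missing:
        raise ValidationError(f"MDL missing for {missing}")
    mdl = np.array([matrix.mdl[m] for m in matrix.metals])
    if np.any(mdl <= 0):
        raise ValidationError("MDL values must be positive")
    raw = matrix.raw if matrix.raw is not None else matrix.values
    below = raw <= mdl[None, :]
    alpha = np.where(below, (5.0 / 6.0) * mdl[None, :], 0.05 * matrix.values + mdl[None, :])
    return UncertaintyMatrix(alpha=alpha, metals=matrix.metals)


def _q_values(x: np.ndarray, gf: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    r = (x - gf) / alpha
    r2 = r * r
    abs_r = np.abs(r)
    robust = np.where(abs_r > ROBUST_CUTOFF, ROBUST_CUTOFF * abs_r, r2)
    return float(r2.sum()), float(robust.sum())


def _single_run(
    x: np.ndarray,
    alpha: np.ndarray,
    n_factors: int,
    seed: int,
    robust: bool,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, float, bool, np.ndarray]:
    rng = np.random.default_rng(seed)
    n, m = x.shape
    scale = np.sqrt(max(x.mean(), _EPS) / n_factors)
    g = rng.uniform(0.1, 1.0, size=(n, n_factors)) * scale
    f = rng.uniform(0.1, 1.0, size=(n_factors, m)) * scale

    w_base = 1.0 / (alpha * alpha)
    w = w_base
    history = []
    prev_obj = np.inf
    converged = False
    for it in range(max_iter):
        if robust:
            r = np.abs(x - g @ f) / alpha
            # IRLS: down-weight cells past the outlier cutoff
            w = w_base * np.where(
                r > ROBUST_CUTOFF, ROBUST_CUTOFF / np.maximum(r, _EPS), 1.0
            )
        wx = w * x
        gf = g @ f
        g *= (wx @ f.T) / ((w * gf) @ f.T + _EPS)
        gf = g @ f
        f *= (g.T @ wx) / (g.T @ (w * gf) + _EPS)
        q_true, q_rob = _q_values(x, g @ f, alpha)
        obj = q_rob if robust else q_true
        history.append(q_true)
        if not np.isfinite(obj):
            break
        if it > 10 and abs(prev_obj - obj) <= tol * max(prev_obj, _EPS):
            converged = True
            break
        prev_obj = obj
    q_true, q_rob = _q_values(x, g @ f, alpha)
    return g, f, q_true, q_rob, converged, np.asarray(history)


def fit_pmf(
    matrix: SampleMatrix,
    alpha: UncertaintyMatrix,
    n_factors: int,
    n_runs: int = 20,
    seed: int = 0,
    robust: bool = True,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> FactorSolution:
    """Best-of-``n_runs`` weighted NMF minimising Q; lowest Q_robust wins."""
    x = matrix.values
    a = np.asarray(alpha.alpha, float)
    if a.shape != x.shape:
        raise ValidationError("uncertainty matrix shape mismatch")
    if not 1 <= n_factors <= x.shape[1]:
        raise ValidationError(f"n_factors must be in [1, {x.shape[1]}]")
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")

    best = None
    per_run = []
    n_converged = 0
    for run in range(n_runs):
        run_seed = seed + run
        g, f, q_true, q_rob, converged, hist = _single_run(
            x, a, n_factors, run_seed, robust, max_iter, tol
        )
        ok = np.isfinite(q_rob)  # hitting max_iter is an accepted stop
        per_run.append(
            {"seed": run_seed, "q_true": q_true, "q_robust": q_rob, "converged": converged}
        )
        if ok:
            if converged:
                n_converged += 1
            if best is None or q_rob < best[3]:
                best = (g, f, q_true, q_rob, run_seed, hist)
    if best is None:
        raise PmfConvergenceError(
            f"no run reached a finite objective within {max_iter} iterations", per_run
        )
    g, f, q_true, q_rob, best_seed, hist = best
    return FactorSolution(
        g=g,
        f=f,
        q_true=q_true,
        q_robust=q_rob,
        n_factors=n_factors,
        metals=matrix.metals,
        seed_of_best=best_seed,
        n_converged=n_converged,
        q_history=hist,
    )


def factor_contributions(solution: FactorSolution) -> pd.DataFrame:
    """Percent of each metal's modelled mass attributed to each factor.

    Columns (metals) sum to 100.
    """
    mass = solution.g.sum(axis=0)[:, None] * solution.f  # (factors, metals)
    totals = mass.sum(axis=0)
    if np.any(totals <= 0):
        dead = [m.value for m, t in zip(solution.metals, totals) if t <= 0]
        raise ValidationError(f"no modelled mass for {dead}; contributions undefined")
    pct = 100.0 * mass / totals[None, :]
    return pd.DataFrame(
        pct,
        index=[f"factor_{a + 1}" for a in range(solution.n_factors)],
        columns=[m.value for m in solution.metals],
    )


def diagnostics(
    matrix: SampleMatrix, alpha: UncertaintyMatrix, solution: FactorSolution
) -> dict:
    """Per-metal R^2 (observed vs predicted) and scaled-residual summary."""
    x = matrix.values
    pred = solution.predicted
    r2 = {}
    for j, metal in enumerate(solution.metals):
        obs, fit = x[:, j], pred[:, j]
        if np.std(obs) == 0 or np.std(fit) == 0:
            r2[metal.value] = float("nan")
        else:
            r2[metal.value] = float(np.corrcoef(obs, fit)[0, 1] ** 2)
    scaled = (x - pred) / np.asarray(alpha.alpha)
    within = float(np.mean(np.abs(scaled) <= 3.0))
    return {
        "r2_per_metal": r2,
        "scaled_residuals": scaled,
        "fraction_within_3": within,
    }
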
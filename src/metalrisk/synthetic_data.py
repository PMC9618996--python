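"""Synthetic sample-level data generators.

Two generators back the testable surface of the receptor-model and pattern
analyses, for which only summary statistics are published:

* ``simulate_samples`` draws per-species concentration samples from a
  truncated normal (or truncated lognormal) whose *post-truncation* mean and
  SD are solved numerically to match the published summary, and whose support
  is the published [min, max] range. The published statistics describe the
  observed samples, so the truncated moments — not the parent parameters —
  are matched.
* ``simulate_factor_data`` builds factor-structured mixtures X = G.F with
  known non-negative contributions and profiles, perturbed by multiplicative
  lognormal noise of a given coefficient of variation; ground truth is kept
  for recovery tests.

``censor_below_mdl`` applies detection-limit censoring: cells at or below
the MDL are flagged and the working value is replaced by MDL/2 (the usual
receptor-modelling substitution), with the raw values retained for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .core_tables import (
    ConcentrationSummary,
    Metal,
    METALS,
    SampleMatrix,
    ValidationError,
    summary_mean_frame,
)

__all__ = [
    "SimulationSpec",
    "FactorTruth",
    "simulate_samples",
    "simulate_factor_data",
    "censor_below_mdl",
    "truncated_normal_params",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for a sample-level concentration matrix."""

    target: Sequence[ConcentrationSummary]
    n_per_species: int
    distribution: str = "truncated_normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_species < 2:
            raise ValidationError("n_per_species must be >= 2")
        if self.distribution not in ("truncated_normal", "truncated_lognormal"):
            raise ValidationError(f"unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class FactorTruth:
    """Known source structure for factor-model recovery tests."""

    g_true: np.ndarray  # (n_samples, n_factors), contributions >= 0
    f_true: np.ndarray  # (n_factors, n_metals), profiles >= 0
    noise_cv: float = 0.0
    mdl: Mapping[Metal, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.g_true, float)
        f = np.asarray(self.f_true, float)
        if g.ndim != 2 or f.ndim != 2 or g.shape[1] != f.shape[0]:
            raise ValidationError("g_true/f_true dimensions inconsistent")
        if np.any(g < 0) or np.any(f < 0):
            raise ValidationError("factor truth must be non-negative")
        if np.any(np.all(f == 0, axis=1)):
            raise ValidationError("a profile row is identically zero")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


def _truncnorm_sd_bounds(a: float, b: float) -> float:
    # sup of the truncated-normal SD on [a, b] (approached as sigma -> inf,
    # i.e. the uniform limit is exceeded toward the two-point bound (b-a)/2)
    return (b - a) / 2.0


def truncated_normal_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) of a normal truncated to [lo, hi] whose truncated
    mean/SD best match the targets.

    Solved by least squares on the analytic truncated moments. Targets with an
    SD unattainable on the given support are matched as closely as possible
    (the residual lands on the feasibility boundary).
    """
    if hi <= lo:
        raise ValidationError(f"degenerate support [{lo}, {hi}]")
    width = hi - lo
    target_sd = min(sd, 0.999 * _truncnorm_sd_bounds(lo, hi))

    key = (mean, sd, lo, hi)
    cached = _TRUNCNORM_CACHE.get(key)
    if cached is not None:
        return cached

    def moments(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = np.exp(np.clip(log_sigma, -30.0, 30.0))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        m, v = float(m), float(v)
        if not (np.isfinite(m) and np.isfinite(v) and v >= 0):
            return np.array([10.0 * width, 10.0 * width])
        return np.array([m - mean, np.sqrt(v) - target_sd])

    x0 = np.array([mean, np.log(max(target_sd, 1e-6 * width))])
    sol = optimize.least_squares(moments, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    mu, sigma = float(sol.x[0]), float(np.exp(np.clip(sol.x[1], -30.0, 30.0)))
    _TRUNCNORM_CACHE[key] = (mu, sigma)
    return mu, sigma


_TRUNCNORM_CACHE: dict[tuple[float, float, float, float], tuple[float, float]] = {}


def _draw_species(
    summary: ConcentrationSummary, n: int, distribution: str, rng: np.random.Generator
) -> np.ndarray:
    mean, sd, lo, hi = summary.mean, summary.sd, summary.min, summary.max
    if hi == lo:
        return np.full(n, mean)
    if sd == 0:
        warnings.warn(
            f"{summary.species}/{summary.metal.value}: sd=0 with min<max; emitting constant samples",
            stacklevel=3,
        )
        return np.full(n, mean)
    if distribution == "truncated_lognormal":
        # work on the log scale; a zero lower bound becomes an open support
        log_lo = np.log(lo) if lo > 0 else -np.inf
        log_hi = np.log(hi)
        # log-scale targets via moment matching of a lognormal
        cv2 = (sd / mean) ** 2
        log_sd = np.sqrt(np.log1p(cv2))
        log_mean = np.log(mean) - 0.5 * log_sd**2
        a = (log_lo - log_mean) / log_sd if np.isfinite(log_lo) else -np.inf
        b = (log_hi - log_mean) / log_sd
        draws = stats.truncnorm.rvs(
            a, b, loc=log_mean, scale=log_sd, size=n, random_state=rng
        )
        return np.exp(draws)
    mu, sigma = truncated_normal_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def simulate_samples(
    spec: SimulationSpec, mdl: Mapping[Metal, float] | None = None
) -> SampleMatrix:
    """Draw an (n_species * n_per_species) x metals sample matrix.

    Every draw lies inside the published [min, max] of its summary; the same
    spec and seed reproduce the matrix bit for bit.
    """
    means = summary_mean_frame(spec.target)  # validates completeness & ordering
    by_species: dict[str, dict[Metal, ConcentrationSummary]] = {}
    for s in spec.target:
        by_species.setdefault(s.species, {})[s.metal] = s

    rng = np.random.default_rng(spec.seed)
    rows: list[np.ndarray] = []
    species_labels: list[str] = []
    for species in means.index:
        block = np.empty((spec.n_per_species, len(METALS)))
        for j, metal in enumerate(METALS):
            block[:, j] = _draw_species(
                by_species[species][metal], spec.n_per_species, spec.distribution, rng
            )
        rows.append(block)
        species_labels.extend([species] * spec.n_per_species)
    values = np.clip(np.vstack(rows), 0.0, None)
    return SampleMatrix(
        values=values,
        species=species_labels,
        mdl=dict(mdl) if mdl else None,
        raw=values.copy(),
    )


def simulate_factor_data(truth: FactorTruth, seed: int = 0) -> SampleMatrix:
    """Generate X = G.F perturbed by multiplicative lognormal noise.

    The noise factor has unit mean and coefficient of variation
    ``truth.noise_cv``; with ``noise_cv=0`` the product is returned exactly.
    """
    g = np.asarray(truth.g_true, float)
    f = np.asarray(truth.f_true, float)
    x = g @ f
    if truth.noise_cv > 0:
        rng = np.random.default_rng(seed)
        log_sd = np.sqrt(np.log1p(truth.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * log_sd**2, sigma=log_sd, size=x.shape)
        x = x * noise
    x = np.clip(x, 0.0, None)
    n = x.shape[0]
    metals = METALS[: x.shape[1]]
    return SampleMatrix(
        values=x,
        species=[f"sample_{i}" for i in range(n)],
        metals=metals,
        mdl=dict(truth.mdl) or None,
        raw=x.copy(),
    )


def censor_below_mdl(matrix: SampleMatrix) -> SampleMatrix:
    """Flag cells at or below the detection limit and substitute MDL/2.

    The branch condition uses the raw (pre-substitution) value; a value
    exactly at the MDL is censored. The input matrix is not modified.
    """
    if matrix.mdl is None:
        raise ValidationError("no MDL configured on the sample matrix")
    missing = [m.value for m in matrix.metals if m not in matrix.mdl]
    if missing:
        raise ValidationError(f"MDL missing for {missing}")
    raw = matrix.raw if matrix.raw is not None else matrix.values
    mdl_vec = np.array([matrix.mdl[m] for m in matrix.metals])
    if np.any(mdl_vec <= 0):
        raise ValidationError("MDL values must be positive")
    below = raw <= mdl_vec[None, :]
    values = raw.copy()
    values[below] = (mdl_vec[None, :] / 2.0 * np.ones_like(raw))[below]
    return SampleMatrix(
        values=values,
        species=list(matrix.species),
        metals=matrix.metals,
        mdl=dict(matrix.mdl),
        below_mdl=below,
        raw=raw.copy(),
    )
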
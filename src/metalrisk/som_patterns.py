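"""Self-organizing map (SOM) training and component-plane extraction.

A SOM summarises a standardized samples-by-metals matrix on a small 2-D
grid of codebook vectors. Each metal's slice of the codebook, reshaped to
the grid, is its *component plane*; metals whose planes show analogous
gradients (positive plane correlation) co-occur across samples, while
anti-parallel gradients indicate opposition.

Map size follows the common heuristic m = 5 * sqrt(n) nodes for n samples,
with the grid chosen as the factor pair closest to m at aspect ratio <= 2.
Training is the deterministic batch algorithm with a Gaussian neighbourhood
whose radius decays linearly from max(rows, cols)/2 to 1 over the epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_tables import Metal, ValidationError

__all__ = [
    "SomModel",
    "grid_size",
    "standardize",
    "train_som",
    "component_planes",
    "plane_correlations",
]


@dataclass
class SomModel:
    grid_rows: int
    grid_cols: int
    codebook: np.ndarray  # (nodes, n_vars), standardized units
    bmu: np.ndarray  # per-sample best-matching node index
    quantization_error: float
    qe_history: np.ndarray
    seed: int
    columns: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols


def grid_size(n_samples: int) -> tuple[int, int]:
    """Grid (rows, cols) for ~5*sqrt(n) nodes, aspect ratio <= 2, cols >= rows.

    Ties on |rows*cols - m| go to the wider grid.
    """
    if n_samples < 4:
        raise ValidationError("need at least 4 samples for a SOM")
    m = int(round(5.0 * np.sqrt(n_samples)))
    best: tuple[int, int] | None = None
    best_key: tuple[float, float] | None = None
    for rows in range(1, m + 1):
        if rows * rows > 2 * m + rows:  # beyond this no candidate can win
            break
        for cols in range(rows, 2 * rows + 1):
            if cols / rows > 2:
                continue
            key = (abs(rows * cols - m), -cols / rows)  # tie -> wider
            if best_key is None or key < best_key:
                best_key, best = key, (rows, cols)
    assert best is not None
    return best


def standardize(x: np.ndarray) -> np.ndarray:
    """Column z-scores; constant columns are rejected."""
    x = np.asarray(x, float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValidationError(f"constant column(s) at index {np.where(sd == 0)[0].tolist()}")
    return (x - x.mean(axis=0)) / sd


def train_som(
    x: np.ndarray,
    grid: tuple[int, int],
    epochs: int = 500,
    seed: int = 0,
    columns: tuple[str, ...] | None = None,
) -> SomModel:
    """Batch-train a SOM on standardized data (rows = samples)."""
    x = np.asarray(x, float)
    if x.ndim != 2:
        raise ValidationError("expected a 2-D samples-by-variables matrix")
    if np.any(x.std(axis=0) == 0) and x.shape[0] > 1:
        raise ValidationError("standardize the input first (constant column found)")
    rows, cols = grid
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)

    # node coordinates on the grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

    # init: random sample draws (with replacement if nodes > samples)
    codebook = x[rng.integers(0, x.shape[0], size=n_nodes)].copy()
    # per-node scalar jitter breaks duplicate-row ties while keeping
    # duplicated/permuted columns exactly equivalent
    codebook += rng.normal(0.0, 1e-3, (n_nodes, 1))

    radius_start = max(rows, cols) / 2.0
    qe_hist = np.empty(epochs)
    bmu = np.zeros(x.shape[0], dtype=int)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = max(radius_start + (1.0 - radius_start) * frac, 1e-6)
        d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
        bmu = d2.argmin(axis=1)
        qe_hist[epoch] = float(np.sqrt(d2[np.arange(x.shape[0]), bmu]).mean())
        h = np.exp(-grid_d2[:, bmu] / (2.0 * sigma * sigma))  # (nodes, samples)
        denom = h.sum(axis=1)
        num = h @ x
        nonempty = denom > 1e-12
        codebook[nonempty] = num[nonempty] / denom[nonempty, None]
    d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    bmu = d2.argmin(axis=1)
    qe = float(np.sqrt(d2[np.arange(x.shape[0]), bmu]).mean())
    if columns is None:
        columns = tuple(m.value for m in Metal)[: x.shape[1]]
    return SomModel(
        grid_rows=rows,
        grid_cols=cols,
        codebook=codebook,
        bmu=bmu,
        quantization_error=qe,
        qe_history=qe_hist,
        seed=seed,
        columns=tuple(columns),
    )


def component_planes(model: SomModel) -> dict[str, np.ndarray]:
    """Each variable's codebook column reshaped to the grid."""
    return {
        name: model.codebook[:, j].reshape(model.grid_rows, model.grid_cols)
        for j, name in enumerate(model.columns)
    }


def plane_correlations(model: SomModel) -> pd.DataFrame:
    """Pearson correlations between flattened component planes."""
    flat = model.codebook  # (nodes, vars); columns are flattened planes
    r = np.corrcoef(flat, rowvar=False)
    return pd.DataFrame(r, index=model.columns, columns=model.columns)
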
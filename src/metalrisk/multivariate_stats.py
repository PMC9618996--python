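"""Correlation, sampling-adequacy tests, PCA and hierarchical clustering.

These run on the species-mean matrix of a food class (species as rows,
metals as columns): the Pearson correlation matrix, Bartlett's test of
sphericity, the Kaiser-Meyer-Olkin (KMO) sampling-adequacy statistic, PCA
on the correlation matrix with eigenvalue-greater-than-1 retention and
|loading| > 0.5 salience, and Ward-linkage agglomerative clustering of the
metals on their standardized profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_tables import ValidationError

__all__ = [
    "PcaResult",
    "pearson_matrix",
    "bartlett_sphericity",
    "kmo",
    "pca",
    "hcluster",
    "cluster_labels",
]


def _as_frame(x) -> pd.DataFrame:
    df = pd.DataFrame(x)
    if df.shape[0] < 3:
        raise ValidationError("need at least 3 rows")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        raise ValidationError(f"constant column(s): {constant}")
    return df.astype(float)


def pearson_matrix(x) -> pd.DataFrame:
    """Pearson correlation matrix of the columns."""
    return _as_frame(x).corr(method="pearson")


def bartlett_sphericity(x) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R|, df = p(p-1)/2.
    """
    df = _as_frame(x)
    n, p = df.shape
    r = df.corr().to_numpy()
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValidationError("correlation matrix is singular")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    dof = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, dof))
    return float(chi2), dof, pval


def kmo(x) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    Contrasts off-diagonal correlations r_ij with the anti-image partial
    correlations q_ij obtained from the inverse correlation matrix.
    """
    df = _as_frame(x)
    r = df.corr().to_numpy()
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        raise ValidationError("correlation matrix is singular") from None
    d = np.sqrt(np.diag(rinv))
    q = -rinv / np.outer(d, d)
    mask = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[mask] ** 2).sum()
    q2 = (q[mask] ** 2).sum()
    return float(r2 / (r2 + q2))


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # variables x components, scaled by sqrt(eigenvalue)
    explained_pct: np.ndarray
    cumulative_pct: np.ndarray
    retained: list[int]  # 0-based component indices with eigenvalue > 1
    salient_loadings: pd.DataFrame  # |loading| > 0.5 mask


def pca(x) -> PcaResult:
    """PCA of the correlation matrix (variables standardized implicitly).

    Loadings are eigenvectors scaled by the square root of their eigenvalue;
    each component's sign is fixed so its largest-magnitude loading is
    positive.
    """
    df = _as_frame(x)
    r = df.corr().to_numpy()
    eigval, eigvec = np.linalg.eigh(r)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = eigvec * np.sqrt(np.clip(eigval, 0, None))[None, :]
    comp_names = [f"PC{j + 1}" for j in range(len(eigval))]
    loadings_df = pd.DataFrame(loadings, index=df.columns, columns=comp_names)
    explained = 100.0 * eigval / eigval.sum()
    return PcaResult(
        eigenvalues=eigval,
        loadings=loadings_df,
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
        retained=[j for j, ev in enumerate(eigval) if ev > 1.0],
        salient_loadings=loadings_df.abs() > 0.5,
    )


def hcluster(x) -> tuple[np.ndarray, list[str]]:
    """Ward-linkage clustering of the variables (columns).

    Variables are z-scored down their rows first so clustering reflects the
    shape of each metal's profile across species, not its scale. Returns the
    scipy linkage matrix and the variable labels.
    """
    df = _as_frame(x)
    z = (df - df.mean()) / df.std(ddof=0)
    profiles = z.to_numpy().T  # variables as observations
    link = hierarchy.linkage(pdist(profiles, metric="euclidean"), method="ward")
    return link, [str(c) for c in df.columns]


def cluster_labels(link: np.ndarray, labels: list[str], k: int) -> dict[str, int]:
    """Cut the dendrogram into k groups; returns variable -> group id."""
    assign = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return {lab: int(g) for lab, g in zip(labels, assign)}
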
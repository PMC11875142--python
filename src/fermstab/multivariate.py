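"""Standardisation, PCA and k-means for fermentation performance data.

The five steady-state performance parameters (stability duration,
Yield(X/S), Yield(P/S), specific uptake, specific productivity) have
incommensurate units, so the PCA operates on the correlation structure:
columns are z-scored and the eigendecomposition is of the resulting
sample correlation matrix.  A fixed sign convention (largest-magnitude
loading entry positive) makes loadings reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "PERFORMANCE_PARAMETERS",
    "PCAResult",
    "ClusterModel",
    "standardize",
    "pca",
    "kmeans",
    "cluster_condition_crosstab",
    "performance_matrix",
]

#: The PCA parameter set, in column order.
PERFORMANCE_PARAMETERS = (
    "stability_duration",
    "yield_xs",
    "yield_ps",
    "specific_uptake",
    "specific_productivity",
)


def performance_matrix(records, parameters=PERFORMANCE_PARAMETERS) -> np.ndarray:
    """Stack the chosen performance parameters into an (n, p) matrix."""
    return np.array([[getattr(r, p) for p in parameters] for r in records], float)


def standardize(matrix):
    """Z-score columns to mean 0 and sample standard deviation 1 (ddof=1).

    Returns ``(z, means, scales)``.  A zero-variance column is rejected by
    name (index) since it cannot be scored.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(scales == 0)
    if dead.size:
        raise ValueError(f"zero-variance column(s) {dead.tolist()} cannot be standardized")
    return (X - means) / scales, means, scales


@dataclass
class PCAResult:
    parameter_names: tuple
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray           # (n_components, n_parameters), rows orthonormal
    variance_fractions: np.ndarray  # per retained component
    scores: np.ndarray             # (n_samples, n_components)

    @property
    def cumulative_variance(self) -> float:
        return float(self.variance_fractions.sum())


def pca(matrix, n_components=None, parameter_names=None) -> PCAResult:
    """PCA of the correlation structure of ``matrix``.

    ``matrix`` holds raw (unstandardised) columns; standardisation is
    applied internally.  Components are eigenvectors of the sample
    correlation matrix, ordered by decreasing eigenvalue; variance
    fractions are eigenvalues over the total (= number of parameters).
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n_components is None:
        n_components = p
    if n_components > p:
        raise ValueError("cannot retain more components than parameters")
    Z, means, scales = standardize(X)
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    loadings = eigvecs.T[:n_components]
    # sign convention: the largest-magnitude entry of each loading is positive
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    scores = Z @ loadings.T
    if parameter_names is None:
        parameter_names = tuple(f"x{i}" for i in range(p))
    return PCAResult(
        parameter_names=tuple(parameter_names),
        means=means, scales=scales,
        loadings=loadings,
        variance_fractions=np.clip(eigvals[:n_components], 0, None) / p,
        scores=scores,
    )


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray  # 0-based cluster index per point
    inertia: float


def kmeans(points, k=3, seed=0, n_init=50) -> ClusterModel:
    """Best-of-``n_init`` Lloyd's k-means, deterministic for a given seed."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k > len(X):
        raise ValueError("k must not exceed the number of points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed,
                algorithm="lloyd").fit(X)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=km.labels_.astype(int),
        inertia=float(km.inertia_),
    )


def cluster_condition_crosstab(model: ClusterModel, records) -> pd.DataFrame:
    """Contingency table of cluster membership by operating condition.

    Conditions are the distinct (dilution rate, temperature) pairs of the
    records.  Used to check whether unsupervised clusters align with the
    experimental design factors.
    """
    records = list(records)
    if len(records) != len(model.assignments):
        raise ValueError("records and assignments must align")
    cond = [f"D={r.dilution_rate:g},T={r.temperature:g}" for r in records]
    return pd.crosstab(
        pd.Series(model.assignments, name="cluster"),
        pd.Series(cond, name="condition"),
    )
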
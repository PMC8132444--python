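"""Generalized Laplacian embedding and k-means assignment.

From the signed incidence matrix ``W`` we form the generalized Laplacian
``L' = D' - W`` with ``D'`` the diagonal of row sums. The k-dimensional
feature vector of cell ``i`` is the i-th row of the matrix whose columns
are unit eigenvectors of the k algebraically smallest eigenvalues of
``L'`` — the minimizer of ``tr(Z L' Z^T)`` over orthonormal k-frames.
When ``W`` has negative entries ``L'`` can be indefinite, so eigenvalues
are ordered by value, never by magnitude. Clusters come from k-means
(squared Euclidean, k-means++ seeding, multiple restarts) on the rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .affinity import IncidenceMatrix

__all__ = [
    "GeneralizedLaplacian",
    "Embedding",
    "ClusterAssignment",
    "build_generalized_laplacian",
    "spectral_embed",
    "kmeans_assign",
]


@dataclass
class GeneralizedLaplacian:
    """``L' = diag(rowsums(W)) - W``; rows sum to zero."""

    lap: np.ndarray
    degree: np.ndarray

    def __post_init__(self) -> None:
        self.lap = np.asarray(self.lap, dtype=float)
        self.degree = np.asarray(self.degree, dtype=float)
        if np.abs(self.lap.sum(axis=1)).max() > 1e-10:
            raise ValueError("Laplacian rows must sum to 0")


@dataclass
class Embedding:
    """Cells x k spectral feature matrix with its ascending eigenvalues."""

    features: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.features.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("feature columns must match eigenvalue count")
        if np.any(np.diff(self.eigenvalues) < -1e-10):
            raise ValueError("eigenvalues must be ascending")
        gram = self.features.T @ self.features
        if np.abs(gram - np.eye(gram.shape[0])).max() > 1e-8:
            raise ValueError("feature columns must be orthonormal")


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k) per cell, with the seed that produced them."""

    cell_ids: list[str]
    labels: np.ndarray
    k: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.cell_ids) != self.labels.shape[0]:
            raise ValueError("cell_ids and labels differ in length")
        if self.labels.size and not (1 <= self.labels.min() and self.labels.max() <= self.k):
            raise ValueError("labels must lie in 1..k")


def build_generalized_laplacian(w: IncidenceMatrix | np.ndarray) -> GeneralizedLaplacian:
    """Form ``L' = D' - W`` from a symmetric (possibly signed) incidence matrix."""
    mat = w.w if isinstance(w, IncidenceMatrix) else np.asarray(w, dtype=float)
    if np.abs(mat - mat.T).max() > 1e-12:
        raise ValueError("incidence matrix must be symmetric (within 1e-12)")
    degree = mat.sum(axis=1)
    lap = np.diag(degree) - mat
    return GeneralizedLaplacian(lap, degree)


def spectral_embed(lap: GeneralizedLaplacian, k: int) -> Embedding:
    """Eigenvectors of the k algebraically smallest eigenvalues of ``L'``.

    A full symmetric eigendecomposition is used; all target problem sizes
    (up to a few thousand cells) are comfortably dense. The trivial
    near-constant eigenvector is retained and no row normalization is
    applied to the embedding.
    """
    n = lap.lap.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")
    eigvals, eigvecs = eigh(lap.lap, subset_by_index=(0, k - 1))
    return Embedding(eigvecs, eigvals)


def kmeans_assign(
    emb: Embedding,
    k: int,
    seed: int = 0,
    restarts: int = 50,
    cell_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Cluster embedding rows with k-means; best of ``restarts`` k-means++ runs.

    Deterministic given ``(seed, restarts)``. Warns if fewer than ``k``
    clusters end up non-empty.
    """
    x = emb.features
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct embedding rows")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x) + 1
    occupied = np.unique(labels)
    if occupied.size < k:
        empty = sorted(set(range(1, k + 1)) - set(occupied.tolist()))
        warnings.warn(f"empty cluster(s): {empty}", stacklevel=2)
    ids = cell_ids if cell_ids is not None else [str(i) for i in range(n)]
    return ClusterAssignment(list(ids), labels, k, seed)
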
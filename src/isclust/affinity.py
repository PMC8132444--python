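"""Cell-cell rank correlation and the signed incidence matrix.

Cells with the same identity tend to rank the same genes highly, so
Spearman's rho across genes is a natural similarity; a rho near -1 marks
an opposite expression trend, i.e. a dissimilar pair. The positive part
of the correlation matrix is sparsified to each cell's top-``h``
neighbors, the negative part to each cell's top-``q`` most-negative
partners (both union-symmetrized), and the two are fused into a signed
incidence matrix

    W = (1 - omega) * S + omega * DS,   0 <= omega <= 1,

where ``w_ij > 0`` means similar, ``w_ij < 0`` distant, and ``w_ij = 0``
irrelevant. ``omega = 0`` recovers the nonnegative affinity of
conventional spectral clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.io import mmwrite
from scipy.stats import rankdata

from .io_prep import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "SimilarityMatrix",
    "DissimilarityMatrix",
    "IncidenceMatrix",
    "pairwise_correlation",
    "split_similarity_dissimilarity",
    "build_similarity_matrix",
    "build_dissimilarity_matrix",
    "build_incidence_matrix",
    "write_edge_list",
    "write_matrix_market",
]


@dataclass
class CorrelationMatrix:
    """Symmetric n x n matrix of pairwise cell correlations in [-1, 1]."""

    rho: np.ndarray
    cell_ids: list[str]
    method: str = "spearman"

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.cell_ids)
        if self.rho.shape != (n, n):
            raise ValueError("rho must be square and match cell_ids")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(self.rho), 1.0):
            raise ValueError("correlation diagonal must be 1")


@dataclass
class SimilarityMatrix:
    """Sparse nonnegative similarity graph: each cell's top-``h`` positive partners."""

    s: np.ndarray
    h: int

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s < 0):
            raise ValueError("similarity entries must be nonnegative")
        if np.any(np.diag(self.s) != 0):
            raise ValueError("similarity diagonal must be 0")


@dataclass
class DissimilarityMatrix:
    """Sparse nonpositive dissimilarity graph: each cell's top-``q`` negative partners."""

    ds: np.ndarray
    q: int

    def __post_init__(self) -> None:
        self.ds = np.asarray(self.ds, dtype=float)
        if np.any(self.ds > 0):
            raise ValueError("dissimilarity entries must be nonpositive")
        if np.any(np.diag(self.ds) != 0):
            raise ValueError("dissimilarity diagonal must be 0")


@dataclass
class IncidenceMatrix:
    """Signed incidence matrix ``W = (1-omega) S + omega DS`` with its provenance."""

    w: np.ndarray
    omega: float
    h: int
    q: int

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega={self.omega} outside [0, 1]")
        if not np.allclose(self.w, self.w.T, atol=1e-12):
            raise ValueError("incidence matrix must be symmetric")


def pairwise_correlation(expr: ExpressionMatrix, method: str = "spearman") -> CorrelationMatrix:
    """Correlate every pair of cell columns across all genes.

    Spearman uses midranks (average ranks on ties), which coincides with
    the classical ``1 - 6*sum(d^2)/(m(m^2-1))`` formula on tie-free data;
    single-cell zeros make ties pervasive, so midranks are essential.

    Raises if any cell has a constant expression column, for which
    correlation is undefined.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    v = expr.values
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if expr.n_genes < 3:
        raise ValueError("need at least 3 genes")
    ptp = v.max(axis=0) - v.min(axis=0)
    if np.any(ptp == 0):
        bad = [expr.cell_ids[i] for i in np.flatnonzero(ptp == 0)]
        raise ValueError(f"constant expression column(s), correlation undefined: {bad}")
    data = rankdata(v, axis=0) if method == "spearman" else v
    rho = np.corrcoef(data, rowvar=False)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(rho, list(expr.cell_ids), method)


def split_similarity_dissimilarity(rho: CorrelationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Split rho into its positive (similarity) and negative (dissimilarity) parts.

    Diagonals are forced to 0; off the diagonal the two parts sum back to rho.
    """
    r = rho.rho.copy()
    np.fill_diagonal(r, 0.0)
    s_part = np.where(r > 0, r, 0.0)
    ds_part = np.where(r < 0, r, 0.0)
    return s_part, ds_part


def _union_top_mask(values: np.ndarray, width: int, negative: bool) -> np.ndarray:
    """Boolean mask keeping (i, j) if j is in i's top-``width`` list or vice versa.

    Only strictly positive (or, for ``negative=True``, strictly negative)
    entries are eligible; ties in a sorted list break by ascending cell
    index; a cell with fewer eligible partners than ``width`` contributes
    all of them.
    """
    n = values.shape[0]
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        row = values[i]
        elig = np.flatnonzero(row < 0) if negative else np.flatnonzero(row > 0)
        elig = elig[elig != i]
        if elig.size == 0:
            continue
        key = row[elig] if negative else -row[elig]
        order = elig[np.lexsort((elig, key))]
        mask[i, order[:width]] = True
    return mask | mask.T


def build_similarity_matrix(s_part: np.ndarray, h: int) -> SimilarityMatrix:
    """Keep each pair's similarity iff one cell ranks the other in its top ``h``."""
    n = s_part.shape[0]
    if not 1 <= h <= n - 1:
        raise ValueError(f"h={h} outside [1, n-1] for n={n}")
    mask = _union_top_mask(s_part, h, negative=False)
    return SimilarityMatrix(np.where(mask, s_part, 0.0), h)


def build_dissimilarity_matrix(ds_part: np.ndarray, q: int) -> DissimilarityMatrix:
    """Mirror of the similarity construction on the most-negative partners.

    ``q = 0`` yields the zero matrix (pure conventional spectral clustering).
    """
    n = ds_part.shape[0]
    if not 0 <= q <= n - 1:
        raise ValueError(f"q={q} outside [0, n-1] for n={n}")
    if q == 0:
        return DissimilarityMatrix(np.zeros_like(ds_part), 0)
    mask = _union_top_mask(ds_part, q, negative=True)
    return DissimilarityMatrix(np.where(mask, ds_part, 0.0), q)


def build_incidence_matrix(
    s: SimilarityMatrix, ds: DissimilarityMatrix, omega: float
) -> IncidenceMatrix:
    """Fuse similarity and dissimilarity graphs: ``W = (1-omega) S + omega DS``."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega={omega} outside [0, 1]")
    if s.s.shape != ds.ds.shape:
        raise ValueError("similarity and dissimilarity shapes differ")
    w = (1.0 - omega) * s.s + omega * ds.ds
    return IncidenceMatrix(w, omega, s.h, ds.q)


def write_edge_list(matrix: np.ndarray, cell_ids: list[str], path: str | Path) -> None:
    """Write the nonzero upper triangle as a 3-column weighted edge list."""
    with open(path, "w") as fh:
        fh.write("cell_i\tcell_j\tweight\n")
        n = matrix.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if matrix[i, j] != 0:
                    fh.write(f"{cell_ids[i]}\t{cell_ids[j]}\t{matrix[i, j]:.12g}\n")


def write_matrix_market(matrix: np.ndarray, path: str | Path) -> None:
    mmwrite(str(path), coo_matrix(np.triu(matrix)), precision=12)
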
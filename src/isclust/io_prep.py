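"""Expression-matrix I/O, cell quality control and preprocessing.

The preprocessing pipeline mirrors the standard three-step cleanup for
TPM-quantified single-cell RNA-seq data:

1. drop cells that fail sequencing-quality thresholds (total reads,
   mapping rate, detected genes, intergenic fraction),
2. zero unreliable TPM values, ``log2(TPM + 1)``-transform, and drop
   genes detected in too small a fraction of cells,
3. center every gene across cells and divide by its variance.

An :class:`ExpressionMatrix` carries a ``stage`` flag so each step can
assert it receives data in the state it expects; the only legal
progression is ``raw_tpm -> log2_tpm1 -> normalized``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "ExpressionMatrix",
    "CellQCRecord",
    "QCThresholds",
    "LabelTable",
    "read_expression",
    "write_expression",
    "read_qc_table",
    "write_qc_table",
    "read_labels",
    "write_labels",
    "filter_cells_by_qc",
    "filter_and_transform_genes",
    "normalize_genes",
    "preprocess",
]

log = logging.getLogger(__name__)

STAGES = ("raw_tpm", "log2_tpm1", "normalized")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers and a stage flag.

    Parameters
    ----------
    values
        Dense array of shape ``(n_genes, n_cells)``. Nonnegative while
        ``stage == "raw_tpm"``.
    gene_ids, cell_ids
        Ordered, unique identifiers for rows and columns.
    stage
        One of ``raw_tpm``, ``log2_tpm1``, ``normalized``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    stage: str = "raw_tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        _check_unique(self.gene_ids, "gene_id")
        _check_unique(self.cell_ids, "cell_id")
        if self.stage == "raw_tpm" and np.any(self.values < 0):
            raise ValueError("raw TPM values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``keep``, preserving input cell order."""
        keep_set = set(keep)
        missing = keep_set - set(self.cell_ids)
        if missing:
            raise KeyError(f"cell ids not in matrix: {sorted(missing)}")
        idx = [i for i, c in enumerate(self.cell_ids) if c in keep_set]
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.cell_ids[i] for i in idx], self.stage
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CellQCRecord:
    """Per-cell sequencing-quality metrics as emitted by read-level QC tools."""

    cell_id: str
    total_reads: int
    mapping_rate: float
    detected_genes: int
    intergenic_fraction: float

    def __post_init__(self) -> None:
        if self.total_reads < 0 or self.detected_genes < 0:
            raise ValueError(f"{self.cell_id}: counts must be nonnegative")
        for name in ("mapping_rate", "intergenic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.cell_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class QCThresholds:
    """Cutoffs deciding which cells survive quality control.

    A cell is removed when ``total_reads < min_total_reads`` or
    ``mapping_rate < min_mapping_rate`` or ``detected_genes <
    min_detected_genes`` or ``intergenic_fraction >
    max_intergenic_fraction``.
    """

    min_total_reads: int = 300_000
    min_mapping_rate: float = 0.5
    min_detected_genes: int = 2000
    max_intergenic_fraction: float = 0.3


@dataclass
class LabelTable:
    """Cell-to-label assignment used as ground truth or as a prediction."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("cell_ids and labels differ in length")
        _check_unique(self.cell_ids, "cell_id")
        if any(l == "" for l in self.labels):
            raise ValueError("labels must be non-empty strings")

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))

    def reordered(self, cell_ids: Sequence[str]) -> "LabelTable":
        """Return labels reordered to follow ``cell_ids``."""
        m = self.to_dict()
        missing = [c for c in cell_ids if c not in m]
        if missing:
            raise KeyError(f"cells without labels: {missing}")
        return LabelTable(list(cell_ids), [m[c] for c in cell_ids])


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    stage: str = "raw_tpm",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells matrix from TSV/CSV (optionally gzipped) or MatrixMarket.

    Delimited files carry the gene id in the first column and cell ids in
    the header. A ``.mtx`` file (genes as rows) is paired with
    ``genes.tsv`` / ``cells.tsv`` sidecars in the same directory unless
    explicit sidecar paths are given.
    """
    path = Path(path)
    name = path.name.removesuffix(".gz")
    if name.endswith(".mtx"):
        m = mmread(str(path))
        mat = np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "cells.tsv"
        gene_ids = _read_id_column(genes_path)
        cell_ids = _read_id_column(cells_path)
        return ExpressionMatrix(mat, gene_ids, cell_ids, stage)
    sep = "," if name.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns], stage)


def _read_id_column(path: Path) -> list[str]:
    return [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write to TSV/CSV (12 significant digits) or MatrixMarket with id sidecars."""
    path = Path(path)
    name = path.name.removesuffix(".gz")
    if name.endswith(".mtx"):
        mmwrite(str(path), coo_matrix(expr.values), precision=12)
        (path.parent / "genes.tsv").write_text("".join(g + "\n" for g in expr.gene_ids))
        (path.parent / "cells.tsv").write_text("".join(c + "\n" for c in expr.cell_ids))
        return
    sep = "," if name.endswith(".csv") else "\t"
    expr.to_frame().to_csv(path, sep=sep, float_format="%.12g")


def read_qc_table(path: str | Path) -> list[CellQCRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "total_reads", "mapping_rate", "detected_genes", "intergenic_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"QC table missing columns: {sorted(missing)}")
    return [
        CellQCRecord(
            cell_id=str(r.cell_id),
            total_reads=int(r.total_reads),
            mapping_rate=float(r.mapping_rate),
            detected_genes=int(r.detected_genes),
            intergenic_fraction=float(r.intergenic_fraction),
        )
        for r in df.itertuples(index=False)
    ]


def write_qc_table(records: Sequence[CellQCRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "total_reads": [r.total_reads for r in records],
            "mapping_rate": [r.mapping_rate for r in records],
            "detected_genes": [r.detected_genes for r in records],
            "intergenic_fraction": [r.intergenic_fraction for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_labels(path: str | Path) -> LabelTable:
    df = pd.read_csv(path, sep="\t")
    if not {"cell_id", "label"} <= set(df.columns):
        raise ValueError("label table must have columns cell_id, label")
    return LabelTable([str(c) for c in df["cell_id"]], [str(l) for l in df["label"]])


def write_labels(table: LabelTable, path: str | Path) -> None:
    pd.DataFrame({"cell_id": table.cell_ids, "label": table.labels}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing steps
# ---------------------------------------------------------------------------

def filter_cells_by_qc(
    qc: Sequence[CellQCRecord], thresholds: QCThresholds | None = None
) -> tuple[list[str], list[tuple[str, str]]]:
    """Apply the cell-level QC rules.

    Returns the kept cell ids (input order preserved) and a removal
    report listing, for each removed cell, the first failing rule in the
    fixed order reads -> mapping rate -> detected genes -> intergenic
    fraction.
    """
    if not qc:
        raise ValueError("empty QC table")
    _check_unique([r.cell_id for r in qc], "cell_id")
    thr = thresholds or QCThresholds()
    kept: list[str] = []
    removed: list[tuple[str, str]] = []
    for r in qc:
        if r.total_reads < thr.min_total_reads:
            removed.append((r.cell_id, f"total_reads {r.total_reads} < {thr.min_total_reads}"))
        elif r.mapping_rate < thr.min_mapping_rate:
            removed.append((r.cell_id, f"mapping_rate {r.mapping_rate} < {thr.min_mapping_rate}"))
        elif r.detected_genes < thr.min_detected_genes:
            removed.append((r.cell_id, f"detected_genes {r.detected_genes} < {thr.min_detected_genes}"))
        elif r.intergenic_fraction > thr.max_intergenic_fraction:
            removed.append(
                (r.cell_id, f"intergenic_fraction {r.intergenic_fraction} > {thr.max_intergenic_fraction}")
            )
        else:
            kept.append(r.cell_id)
    return kept, removed


def filter_and_transform_genes(
    expr: ExpressionMatrix,
    min_tpm: float = 1.0,
    min_expressed_fraction: float = 0.10,
) -> tuple[ExpressionMatrix, list[str]]:
    """Zero sub-threshold TPM values, log2-transform, drop rarely expressed genes.

    Values below ``min_tpm`` are treated as unreliable and set to 0,
    every value ``v`` becomes ``log2(v + 1)``, and genes nonzero in fewer
    than ``min_expressed_fraction`` of cells are removed. Gene order is
    preserved on the kept set.
    """
    if expr.stage != "raw_tpm":
        raise ValueError(f"expected stage raw_tpm, got {expr.stage}")
    if np.any(expr.values < 0):
        raise ValueError("negative TPM value encountered")
    v = expr.values.copy()
    v[v < min_tpm] = 0.0
    v = np.log2(v + 1.0)
    frac = (v > 0).mean(axis=1)
    keep = frac >= min_expressed_fraction
    if not keep.any():
        raise ValueError(
            "all genes dropped by the expressed-fraction filter; "
            "lower min_expressed_fraction or min_tpm"
        )
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    kept_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(v[keep], kept_ids, list(expr.cell_ids), "log2_tpm1"), dropped


def normalize_genes(
    expr: ExpressionMatrix, scale: str = "variance"
) -> tuple[ExpressionMatrix, list[str]]:
    """Center each gene across cells, then divide by its spread.

    ``scale="variance"`` divides by the sample variance (n-1 denominator);
    ``scale="sd"`` gives the conventional z-score instead. Zero-variance
    genes are removed and reported, keeping downstream rank correlations
    well defined.
    """
    if expr.stage != "log2_tpm1":
        raise ValueError(f"expected stage log2_tpm1, got {expr.stage}")
    if expr.n_cells < 2:
        raise ValueError("normalization requires at least 2 cells")
    if scale not in ("variance", "sd"):
        raise ValueError("scale must be 'variance' or 'sd'")
    var = expr.values.var(axis=1, ddof=1)
    keep = var > 0
    zero_var = [g for g, k in zip(expr.gene_ids, keep) if not k]
    v = expr.values[keep]
    centered = v - v.mean(axis=1, keepdims=True)
    denom = var[keep] if scale == "variance" else np.sqrt(var[keep])
    out = centered / denom[:, None]
    kept_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(out, kept_ids, list(expr.cell_ids), "normalized"), zero_var


def preprocess(
    expr: ExpressionMatrix,
    qc: Sequence[CellQCRecord] | None = None,
    thresholds: QCThresholds | None = None,
    min_tpm: float = 1.0,
    min_expressed_fraction: float = 0.10,
    scale: str = "variance",
) -> ExpressionMatrix:
    """Run the full chain: cell QC, gene filter + log transform, normalization.

    When no QC table is supplied the cell-filtering step is skipped with a
    logged notice (processed public datasets typically arrive pre-filtered).
    """
    if qc is not None:
        kept, removed = filter_cells_by_qc(qc, thresholds)
        if removed:
            log.info("QC removed %d cells", len(removed))
        expr = expr.subset_cells([c for c in expr.cell_ids if c in set(kept)])
    else:
        log.info("no QC table supplied; skipping cell quality filtering")
    expr, dropped = filter_and_transform_genes(expr, min_tpm, min_expressed_fraction)
    if dropped:
        log.info("expressed-fraction filter dropped %d genes", len(dropped))
    expr, zero_var = normalize_genes(expr, scale=scale)
    if zero_var:
        log.info("removed %d zero-variance genes", len(zero_var))
    return expr
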
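"""Planted-cluster scRNA-seq-like data for exercising the whole pipeline.

The generator plants ``k`` cell types in a genes x cells TPM matrix. On
the log2 scale every cell is

    x_gi = mu_g + e_{c(i), g} + eps_gi,

where ``mu_g`` is a gene baseline shared by all cells (variance ``u``),
``e_cg`` is the cell type's signature effect, and ``eps`` is independent
cell noise (unit variance). Signature genes are organized in blocks,
each block up-modulated in one cluster and *inverted* (down-modulated)
in a paired cluster; the inversion is what creates negative
cross-cluster rank correlation, the structure the signed incidence
matrix exists to exploit. The variance split between baseline and
signature blocks is solved from the requested ``within_corr`` and
``cross_corr`` so the generated data realizes those targets
approximately (Spearman on near-Gaussian data tracks the design
correlations closely; dropout shrinks both toward zero). TPM values are
``2**x`` with dropout zeros whose probability falls off quadratically
with the gene's within-cell expression quantile — low-expressed genes
drop out preferentially, as they do in real protocols — averaging
``dropout_rate`` over the matrix.

This is a minimal noise model: it has no library-size variation, batch
structure, or calibrated zero-inflation, so recovery results on it bound
pipeline correctness, not real-data performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io_prep import CellQCRecord, ExpressionMatrix, LabelTable, QCThresholds

__all__ = ["SyntheticSpec", "simulate_expression", "simulate_qc"]


@dataclass
class SyntheticSpec:
    """Parameters of one planted-cluster dataset.

    Defaults describe the reference fixture used throughout the test
    suite: 150 cells, 500 genes, three equal cell types with mean
    within-type Spearman about 0.6, anti-correlated type pairs about
    -0.2, and 30% dropout.
    """

    n_cells: int = 150
    n_genes: int = 500
    k: int = 3
    cluster_props: tuple[float, ...] | None = None
    within_corr: float = 0.6
    cross_corr: float = -0.2
    dropout_rate: float = 0.3
    seed: int = 0
    signature_fraction: float = 0.5
    base_log2_mean: float = 4.0

    def __post_init__(self) -> None:
        if self.cluster_props is None:
            self.cluster_props = tuple(1.0 / self.k for _ in range(self.k))
        if len(self.cluster_props) != self.k:
            raise ValueError("cluster_props length must equal k")
        if abs(sum(self.cluster_props) - 1.0) > 1e-9:
            raise ValueError("cluster_props must sum to 1")
        if not 0.0 < self.within_corr < 1.0:
            raise ValueError("infeasible correlation targets: within_corr must be in (0, 1)")
        if not -1.0 < self.cross_corr < self.within_corr:
            raise ValueError("cross_corr must lie in (-1, within_corr)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_cells < 2 * self.k:
            raise ValueError("need at least 2 cells per cluster")


def _variance_split(spec: SyntheticSpec) -> tuple[float, float]:
    """Solve (baseline variance u, per-block variance v) from the correlation targets.

    With unit cell-noise variance, the design within-type correlation is
    ``(u + n_blocks_per_cluster * v) / (u + n_blocks_per_cluster * v + 1)``
    and the paired-type correlation is ``(u - v) / (...)``.
    """
    w, x = spec.within_corr, spec.cross_corr
    sw = w / (1.0 - w)
    sx = x / (1.0 - w)
    if spec.k == 1:
        return sw, 0.0
    if spec.k == 2:
        u = (sw + sx) / 2.0
        v = (sw - sx) / 2.0
    else:  # ring pairing: every cluster sits in two blocks
        u = (sw + 2.0 * sx) / 3.0
        v = (sw - sx) / 3.0
    if u < 0:
        raise ValueError(
            f"infeasible correlation targets: cross_corr={x} too negative for within_corr={w}"
        )
    return u, v


def _cluster_sizes(n: int, props: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n cells to the cluster proportions."""
    raw = [p * n for p in props]
    sizes = [int(r) for r in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in range(n - sum(sizes)):
        sizes[rema[i % len(rema)]] += 1
    return sizes


def simulate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, LabelTable]:
    """Generate a raw-TPM matrix with planted cell-type labels.

    Deterministic given ``spec.seed``: the same spec yields bit-identical
    matrices.
    """
    rng = np.random.default_rng(spec.seed)
    u, v = _variance_split(spec)
    m, n, k = spec.n_genes, spec.n_cells, spec.k

    sizes = _cluster_sizes(n, spec.cluster_props)
    cluster_of = np.repeat(np.arange(k), sizes)

    mu = spec.base_log2_mean + np.sqrt(u) * rng.standard_normal(m)

    # signature blocks: block b is +a in cluster b and -a in its ring partner
    effects = np.zeros((k, m))
    if k >= 2 and v > 0:
        n_blocks = 1 if k == 2 else k
        n_sig = int(round(spec.signature_fraction * m))
        block_bounds = np.linspace(0, n_sig, n_blocks + 1).astype(int)
        for b in range(n_blocks):
            lo, hi = block_bounds[b], block_bounds[b + 1]
            if hi <= lo:
                continue
            frac = (hi - lo) / m
            # fixed effect magnitude with random sign: keeps the rank
            # correlation close to the designed product-moment value
            amp = np.sqrt(v / frac) * rng.choice([-1.0, 1.0], size=hi - lo)
            effects[b, lo:hi] += amp
            effects[(b + 1) % k, lo:hi] -= amp

    log2_expr = mu[:, None] + effects[cluster_of].T + rng.standard_normal((m, n))
    tpm = np.power(2.0, log2_expr)
    if spec.dropout_rate > 0:
        # P(drop | quantile t within the cell) = 3 d (1-t)^2, mean d
        quantile = (rankdata(log2_expr, axis=0) - 0.5) / m
        p_drop = np.clip(3.0 * spec.dropout_rate * (1.0 - quantile) ** 2, 0.0, 1.0)
        tpm[rng.random((m, n)) < p_drop] = 0.0

    width = len(str(n))
    cell_ids = [f"cell_{i + 1:0{width}d}" for i in range(n)]
    gene_ids = [f"gene_{g + 1:05d}" for g in range(m)]
    labels = LabelTable(cell_ids, [f"type_{c + 1}" for c in cluster_of])
    return ExpressionMatrix(tpm, gene_ids, cell_ids, "raw_tpm"), labels


def simulate_qc(
    cell_ids: list[str],
    n_fail: int = 0,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
) -> list[CellQCRecord]:
    """QC records where exactly ``n_fail`` cells each violate one random rule.

    Passing cells clear every threshold with at least a 10% margin, so
    the QC filter keeps exactly ``len(cell_ids) - n_fail`` cells.
    """
    if n_fail > len(cell_ids):
        raise ValueError("n_fail exceeds number of cells")
    thr = thresholds or QCThresholds()
    rng = np.random.default_rng(seed)
    fail_idx = set(rng.choice(len(cell_ids), size=n_fail, replace=False).tolist())
    records = []
    for i, cid in enumerate(cell_ids):
        rec = CellQCRecord(
            cell_id=cid,
            total_reads=int(rng.integers(int(thr.min_total_reads * 1.2), thr.min_total_reads * 4)),
            mapping_rate=float(rng.uniform(min(thr.min_mapping_rate * 1.1, 0.98), 0.99)),
            detected_genes=int(rng.integers(int(thr.min_detected_genes * 1.2), thr.min_detected_genes * 4)),
            intergenic_fraction=float(rng.uniform(0.005, thr.max_intergenic_fraction * 0.9)),
        )
        if i in fail_idx:
            rule = int(rng.integers(4))
            if rule == 0:
                rec.total_reads = int(rng.integers(0, int(thr.min_total_reads * 0.9)))
            elif rule == 1:
                rec.mapping_rate = float(rng.uniform(0.01, thr.min_mapping_rate * 0.9))
            elif rule == 2:
                rec.detected_genes = int(rng.integers(0, int(thr.min_detected_genes * 0.9)))
            else:
                rec.intergenic_fraction = float(
                    rng.uniform(min(thr.max_intergenic_fraction * 1.1, 0.94), 0.95)
                )
        records.append(rec)
    return records
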
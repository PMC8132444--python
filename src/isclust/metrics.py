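"""External clustering validation: Purity, Rand index, adjusted Rand index, NMI.

All four indices are computed from the contingency table ``T = (t_ij)``
cross-tabulating a predicted partition U against a reference partition V.
Conventions, stated here once:

* NMI uses the natural log (the ratio is base-invariant) and normalizes
  mutual information by the *larger* of the two partition entropies. A
  single-cluster partition has zero entropy and zero mutual information,
  so its NMI is defined as 0.
* ``0 * log 0 := 0`` throughout.
* ARI's 0/0 case (both numerator and denominator zero, which occurs only
  when both partitions are identical trivial partitions — all singletons
  or a single cluster) returns 1 by convention.
* Purity is not symmetric in (U, V): it asks how pure the *predicted*
  clusters are with respect to the reference classes. RI, ARI and NMI
  are symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_prep import LabelTable
from .spectral import ClusterAssignment

__all__ = [
    "ContingencyTable",
    "MetricSet",
    "contingency_table",
    "purity",
    "rand_index",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "evaluate",
]


@dataclass
class ContingencyTable:
    """Nonnegative integer cross-tabulation of predicted vs true clusters."""

    t: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        if self.t.ndim != 2 or np.any(self.t < 0):
            raise ValueError("contingency table must be a 2-D nonnegative integer matrix")

    @property
    def row_sums(self) -> np.ndarray:
        return self.t.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.t.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.t.sum())


@dataclass
class MetricSet:
    """The four external indices for one clustering run."""

    purity: float
    ri: float
    ari: float
    nmi: float

    def as_dict(self) -> dict[str, float]:
        return {"purity": self.purity, "ri": self.ri, "ari": self.ari, "nmi": self.nmi}


def _labels_of(obj) -> tuple[list[str], list]:
    if isinstance(obj, ClusterAssignment):
        return list(obj.cell_ids), list(obj.labels)
    if isinstance(obj, LabelTable):
        return list(obj.cell_ids), list(obj.labels)
    raise TypeError(f"expected ClusterAssignment or LabelTable, got {type(obj)}")


def contingency_table(pred, truth) -> ContingencyTable:
    """Cross-tabulate two partitions of the same cell set.

    Accepts a ``(ClusterAssignment | LabelTable)`` pair, or two plain
    label sequences assumed to be aligned. Rows (predicted clusters) and
    columns (true classes) are ordered by first appearance.
    """
    if isinstance(pred, (ClusterAssignment, LabelTable)) and isinstance(
        truth, (ClusterAssignment, LabelTable)
    ):
        pred_ids, pred_labels = _labels_of(pred)
        truth_ids, truth_labels = _labels_of(truth)
        if set(pred_ids) != set(truth_ids):
            only_pred = sorted(set(pred_ids) - set(truth_ids))
            only_truth = sorted(set(truth_ids) - set(pred_ids))
            raise ValueError(
                f"cell id mismatch; only in prediction: {only_pred}; only in truth: {only_truth}"
            )
        order = {c: i for i, c in enumerate(pred_ids)}
        truth_labels = [x for _, x in sorted(zip(truth_ids, truth_labels), key=lambda p: order[p[0]])]
    else:
        pred_labels, truth_labels = list(pred), list(truth)
        if len(pred_labels) != len(truth_labels):
            raise ValueError("label sequences differ in length")
    return _table_from_sequences(pred_labels, truth_labels)


def _table_from_sequences(pred: Sequence, truth: Sequence) -> ContingencyTable:
    rows: dict = {}
    cols: dict = {}
    for p in pred:
        rows.setdefault(p, len(rows))
    for v in truth:
        cols.setdefault(v, len(cols))
    t = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for p, v in zip(pred, truth):
        t[rows[p], cols[v]] += 1
    return ContingencyTable(t)


def purity(t: ContingencyTable) -> float:
    """Fraction of points whose predicted cluster's majority class they share."""
    n = t.total
    if n < 1:
        raise ValueError("empty contingency table")
    return float(t.t.max(axis=1).sum()) / n


def _pair_counts(t: ContingencyTable) -> tuple[float, float, float, float]:
    """(n11, n00, sum_rows_C2, sum_cols_C2) from contingency-table identities."""

    def c2(x: np.ndarray) -> float:
        x = x.astype(float)
        return float((x * (x - 1) / 2.0).sum())

    n = t.total
    n11 = c2(t.t.ravel())
    sr = c2(t.row_sums)
    sc = c2(t.col_sums)
    pairs = n * (n - 1) / 2.0
    n00 = pairs - sr - sc + n11
    return n11, n00, sr, sc


def rand_index(t: ContingencyTable) -> float:
    """Fraction of point pairs treated concordantly by both partitions."""
    n = t.total
    if n < 2:
        raise ValueError("Rand index requires at least 2 points")
    n11, n00, _, _ = _pair_counts(t)
    return 2.0 * (n00 + n11) / (n * (n - 1))


def adjusted_rand_index(t: ContingencyTable) -> float:
    """Rand index corrected for chance under the hypergeometric null."""
    n = t.total
    if n < 2:
        raise ValueError("adjusted Rand index requires at least 2 points")
    n11, _, sr, sc = _pair_counts(t)
    expected = 2.0 * sr * sc / (n * (n - 1))
    numerator = n11 - expected
    denominator = 0.5 * (sr + sc) - expected
    if denominator == 0.0:
        if numerator == 0.0:
            return 1.0  # identical trivial partitions
        raise ValueError(
            f"ARI undefined: zero denominator with numerator {numerator} "
            f"(row sums {t.row_sums.tolist()}, col sums {t.col_sums.tolist()})"
        )
    return numerator / denominator


def normalized_mutual_information(t: ContingencyTable) -> float:
    """Mutual information normalized by the larger partition entropy."""
    n = t.total
    if n < 1:
        raise ValueError("empty contingency table")
    tij = t.t.astype(float)
    ri = t.row_sums.astype(float)
    cj = t.col_sums.astype(float)
    nz = tij > 0
    mi = float((tij[nz] * np.log(n * tij[nz] / np.outer(ri, cj)[nz])).sum())
    h_rows = float(-(ri[ri > 0] * np.log(ri[ri > 0] / n)).sum())
    h_cols = float(-(cj[cj > 0] * np.log(cj[cj > 0] / n)).sum())
    denom = max(h_rows, h_cols)
    if denom == 0.0:
        return 0.0  # both partitions single-cluster: zero entropy, zero MI
    return mi / denom


def evaluate(pred, truth) -> MetricSet:
    """All four indices for a predicted vs true partition."""
    t = contingency_table(pred, truth)
    return MetricSet(
        purity=purity(t),
        ri=rand_index(t),
        ari=adjusted_rand_index(t),
        nmi=normalized_mutual_information(t),
    )
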
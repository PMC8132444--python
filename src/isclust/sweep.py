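"""Parameter-sweep protocol: grids over (omega, h, q), end-to-end runs,
best-by-metric selection, and the one-tailed Wilcoxon rank-sum comparison
of the signed (ISC) versus conventional (SC) spectral clustering.

The neighborhood-width grid follows the published rule: with ``ns``
cells and ``nt`` cell types, the step size ``ss`` is ``ns`` rounded to
the nearest hundred (ties up) divided by 100, and ``h`` runs from ``ss``
in steps of ``ss`` up to the smallest multiple of ``ss`` at or above
``0.5 * ns / nt``. For each ``h``, ``q`` is either ``h`` or
``floor(h/2)``; omega sweeps ``{0, 0.1, ..., 1}``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from . import affinity, metrics, spectral
from .io_prep import ExpressionMatrix, LabelTable
from .metrics import MetricSet
from .spectral import ClusterAssignment

__all__ = [
    "SweepGrid",
    "SweepRecord",
    "make_parameter_grid",
    "run_isc",
    "sweep_and_select",
    "records_to_frame",
    "best_per_metric",
    "wilcoxon_compare",
    "exceedance_proportion",
]

log = logging.getLogger(__name__)

METRIC_NAMES = ("purity", "ri", "ari", "nmi")
OMEGA_GRID = tuple(round(i / 10, 1) for i in range(11))


@dataclass
class SweepGrid:
    """The (omega, h, q) grid for one dataset."""

    omega_values: tuple[float, ...]
    h_values: tuple[int, ...]
    q_rule: str  # "both" -> q in {h, floor(h/2)}; "equal_h"; "half_h"; "zero"
    ns: int
    nt: int
    ss: int

    def hq_pairs(self) -> list[tuple[int, int]]:
        pairs: list[tuple[int, int]] = []
        for h in self.h_values:
            if self.q_rule in ("both", "equal_h"):
                pairs.append((h, h))
            if self.q_rule in ("both", "half_h"):
                pairs.append((h, h // 2))
            if self.q_rule == "zero":
                pairs.append((h, 0))
        return pairs

    def runs(self) -> list[tuple[float, int, int]]:
        return [(o, h, q) for (h, q) in self.hq_pairs() for o in self.omega_values]


@dataclass
class SweepRecord:
    """One (omega, h, q) evaluation."""

    omega: float
    h: int
    q: int
    metrics: MetricSet | None
    seed: int
    error: str | None = None


def make_parameter_grid(
    ns: int,
    nt: int,
    h_values: tuple[int, ...] | None = None,
    omega_values: tuple[float, ...] = OMEGA_GRID,
    q_rule: str = "both",
) -> SweepGrid:
    """Build the sweep grid for ``ns`` cells and ``nt`` cell types.

    An explicit ``h_values`` override bypasses the step-size rule (some
    published grids deviate from it).
    """
    if nt < 2:
        raise ValueError("need at least 2 cell types")
    if ns < 2 * nt:
        raise ValueError(f"ns={ns} too small for nt={nt} clusters")
    ss = int((ns + 50) // 100)  # nearest hundred, ties up, over 100
    if h_values is not None:
        h_tuple = tuple(int(h) for h in h_values)
        if any(h < 1 for h in h_tuple) or list(h_tuple) != sorted(set(h_tuple)):
            raise ValueError("explicit h_values must be strictly increasing positive ints")
        return SweepGrid(tuple(omega_values), h_tuple, q_rule, ns, nt, ss if ss >= 1 else 1)
    if ss < 1:
        raise ValueError(
            f"step size rounds to 0 for ns={ns}; supply an explicit h_values list"
        )
    upper = 0.5 * ns / nt
    h_max = ss * math.ceil(upper / ss)
    return SweepGrid(tuple(omega_values), tuple(range(ss, h_max + 1, ss)), q_rule, ns, nt, ss)


def run_isc(
    expr: ExpressionMatrix,
    k: int,
    omega: float,
    h: int,
    q: int,
    seed: int = 0,
    restarts: int = 50,
    method: str = "spearman",
) -> ClusterAssignment:
    """One end-to-end clustering: correlation -> S, DS -> W -> L' -> embed -> k-means."""
    if expr.stage != "normalized":
        raise ValueError(f"expected a normalized expression matrix, got stage {expr.stage}")

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"[{name}] {e}") from e

    rho = _stage("correlation", lambda: affinity.pairwise_correlation(expr, method))
    s_part, ds_part = affinity.split_similarity_dissimilarity(rho)
    s = _stage("similarity", lambda: affinity.build_similarity_matrix(s_part, h))
    ds = _stage("dissimilarity", lambda: affinity.build_dissimilarity_matrix(ds_part, q))
    w = _stage("incidence", lambda: affinity.build_incidence_matrix(s, ds, omega))
    lap = _stage("laplacian", lambda: spectral.build_generalized_laplacian(w))
    emb = _stage("embedding", lambda: spectral.spectral_embed(lap, k))
    return _stage(
        "kmeans", lambda: spectral.kmeans_assign(emb, k, seed, restarts, cell_ids=expr.cell_ids)
    )


def sweep_and_select(
    expr: ExpressionMatrix,
    k: int,
    grid: SweepGrid,
    truth: LabelTable,
    seed: int = 0,
    restarts: int = 50,
    method: str = "spearman",
) -> tuple[list[SweepRecord], pd.DataFrame]:
    """Evaluate every (omega, h, q) triple and summarize the best omega per metric.

    For each (h, q) the best omega is reported separately for omega = 0
    (conventional SC) and omega > 0 (signed ISC). Failed runs are recorded
    with an error marker rather than dropped. Per-run k-means seeds are
    ``seed + run_index`` so one global seed reproduces the whole sweep.
    """
    truth = truth.reordered(expr.cell_ids)
    records: list[SweepRecord] = []
    for idx, (omega, h, q) in enumerate(grid.runs()):
        run_seed = seed + idx
        try:
            pred = run_isc(expr, k, omega, h, q, seed=run_seed, restarts=restarts, method=method)
            ms = metrics.evaluate(pred, truth)
            records.append(SweepRecord(omega, h, q, ms, run_seed))
        except Exception as e:  # record, never drop silently
            log.warning("run (omega=%s h=%s q=%s) failed: %s", omega, h, q, e)
            records.append(SweepRecord(omega, h, q, None, run_seed, error=str(e)))
    return records, best_per_metric(records)


def records_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    """Sweep records as a DataFrame sorted by (h, q, omega)."""
    rows = []
    for r in records:
        row = {"omega": r.omega, "h": r.h, "q": r.q, "seed": r.seed, "error": r.error or ""}
        for m in METRIC_NAMES:
            row[m] = getattr(r.metrics, m) if r.metrics is not None else np.nan
        rows.append(row)
    df = pd.DataFrame(rows, columns=["omega", "h", "q", *METRIC_NAMES, "seed", "error"])
    return df.sort_values(["h", "q", "omega"], kind="mergesort").reset_index(drop=True)


def best_per_metric(records: list[SweepRecord]) -> pd.DataFrame:
    """Best omega for each metric within each (h, q), split into SC and ISC.

    ``variant == "sc"`` covers omega = 0 only; ``"isc"`` covers omega > 0.
    """
    df = records_to_frame(records)
    ok = df[df["error"] == ""]
    out = []
    for (h, q), g in ok.groupby(["h", "q"], sort=True):
        for variant, sub in (("sc", g[g["omega"] == 0.0]), ("isc", g[g["omega"] > 0.0])):
            if sub.empty:
                continue
            for m in METRIC_NAMES:
                i = sub[m].idxmax()
                out.append(
                    {
                        "h": h,
                        "q": q,
                        "variant": variant,
                        "metric": m,
                        "omega": sub.loc[i, "omega"],
                        "value": sub.loc[i, m],
                    }
                )
    return pd.DataFrame(out, columns=["h", "q", "variant", "metric", "omega", "value"])


def write_sweep_csv(records: list[SweepRecord], path: str | Path) -> None:
    records_to_frame(records).drop(columns="error").to_csv(path, index=False, float_format="%.6f")


def wilcoxon_compare(isc_best: list[float], sc_best: list[float]) -> float:
    """One-sided Wilcoxon rank-sum p-value for H1: ISC stochastically greater than SC.

    The samples are the best-per-(h, q) metric values of the two
    variants, paired by grid point but compared as two rank-sum samples.
    With at most 12 combined tie-free observations the null is enumerated
    exactly (p = P(W >= w_obs) over all rank assignments); otherwise, and
    whenever ties are present, a tie-corrected normal approximation is
    used (the same policy as R's ``wilcox.test``).
    """
    x = np.asarray(isc_best, dtype=float)
    y = np.asarray(sc_best, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 values per sample")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w_obs = ranks[:nx].sum()
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and nx + ny <= 12:
        total = 0
        ge = 0
        for comb in itertools.combinations(range(nx + ny), nx):
            total += 1
            if ranks[list(comb)].sum() >= w_obs - 1e-12:
                ge += 1
        return ge / total
    # normal approximation with tie correction
    n = nx + ny
    mu = nx * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 0.5  # all observations identical
    z = (w_obs - mu) / math.sqrt(sigma2)
    return float(norm.sf(z))


def exceedance_proportion(isc_best: list[float], sc_best: list[float]) -> float:
    """Auxiliary statistic: fraction of grid points where SC meets or beats ISC."""
    x = np.asarray(isc_best, dtype=float)
    y = np.asarray(sc_best, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float((y >= x).mean())
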
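# Methods

## Model and procedure

Cells of the same type rank largely the same genes highly, so the
rank correlation between two cells' expression profiles is a robust,
monotone-transform-invariant measure of their relationship. For cells
*i*, *j* with *m* genes, Spearman's ρ(i, j) is the product-moment
correlation of the midrank vectors of the two cell columns; on tie-free
data this equals the classical closed form
`1 − 6 Σ d_t² / (m(m² − 1))` with `d_t` the rank difference of gene *t*.
Midranks matter in practice: dropout zeros make ties pervasive in
scRNA-seq, where the no-ties formula is not even well defined. Pearson
correlation is available as an alternative.

The correlation matrix is split by sign: similarities
`s(i,j) = max(ρ, 0)` and dissimilarities `ds(i,j) = min(ρ, 0)`, with
self-pairs excluded (diagonals forced to 0 — self-similarity only shifts
eigenvalues). Each part is sparsified to neighborhoods: the entry (i, j)
of the similarity matrix *S* survives iff *j* is among *i*'s top *h*
positive partners or *i* among *j*'s top *h* (the union rule common to
kNN graph constructions); the dissimilarity matrix *DS* keeps each
cell's *q* most negative partners the same way. Eligibility is strictly
signed: zero entries mean "irrelevant" and are never padded in, and a
cell with fewer than *h* (or *q*) eligible partners contributes all of
them. Ties inside a sorted neighbor list break by ascending cell index,
which makes the construction deterministic under any input ordering.

The signed incidence matrix is the convex combination

    W = (1 − ω) S + ω DS,      0 ≤ ω ≤ 1,

and the generalized Laplacian is L′ = D′ − W with D′ the diagonal of
W's row sums. Minimizing the weighted embedding objective
`½ Σ_ij w_ij ‖z_i − z_j‖²` over orthonormal k-frames is the trace
minimization `min tr(Zᵀ L′ Z)`, solved by the eigenvectors of the *k*
algebraically smallest eigenvalues of L′. Two numerical points follow
from the signs: (1) for ω > 0, L′ can be indefinite, so eigenvalues are
ordered by value, never magnitude — a smallest-magnitude iterative
solver would silently select the wrong subspace; (2) at ω = 0 with
nonnegative *S*, L′ is the familiar PSD graph Laplacian and the
procedure reduces exactly to conventional spectral clustering, a
reduction asserted label-for-label in the tests. A full dense symmetric
eigendecomposition is used; target problems (≤ a few thousand cells)
are small dense matrices. The near-constant trivial eigenvector is
retained among the k features, and no row normalization is applied to
the embedding.

Cluster assignment is k-means on the embedding rows: squared-Euclidean
objective, k-means++ seeding, best of `restarts` runs (default 50,
seed 0, both configurable). The restart count buys stability: a single
k-means replicate on spectral features is noticeably initialization-
sensitive, and all determinism contracts in this package are stated
given (seed, restarts). Degenerate eigenvalue ties are resolved by the
eigensolver's deterministic ordering; tests compare subspaces and
objectives rather than raw eigenvectors, since any rotation within an
eigenspace is equally valid.

## Preprocessing

Inputs are genes × cells TPM matrices (TSV/CSV, optionally gzipped, or
MatrixMarket with id sidecars). Three steps run in a fixed order:

1. **Cell QC** — a cell is removed if total reads < 300 000, mapping
   rate < 0.5, detected genes < 2000, or intergenic fraction > 0.3 (all
   four configurable via `QCThresholds`). The removal report names the
   first failing rule per cell. If no QC table is provided the step is
   skipped with a logged notice, since processed public matrices are
   usually pre-filtered.
2. **Gene filtering + transform** — TPM < 1 is treated as noise and set
   to 0; values become `log2(TPM + 1)`; genes nonzero in < 10% of cells
   are dropped. The fraction filter is idempotent on its kept set.
3. **Normalization** — every gene row is centered by its mean across
   cells and divided by its sample variance (n − 1 denominator). The
   variance (rather than standard deviation) scaling is deliberate and
   kept literal; `scale="sd"` switches to the conventional z-score.
   Zero-variance genes are removed outright rather than left as zero
   rows, which keeps downstream rank correlations well defined.

Correlation is computed on the normalized matrix, after step 3, matching
the pipeline order — even though per-gene scaling alters within-cell
gene ranks, the clustering operates on the data the pipeline actually
produces.

## Validation indices

Purity, RI, ARI and NMI all derive from the contingency table of the
predicted vs reference partition; the module conventions are documented
in `isclust.metrics` (natural-log NMI normalized by the larger partition
entropy, NMI := 0 for single-cluster partitions, ARI := 1 for identical
trivial partitions, 0·log 0 := 0). These conventions are why the
indices are computed in-package; scikit-learn's implementations serve as
independent cross-checks in the test suite, alongside O(N²) all-pairs
and first-principles entropy oracles.

## Sweep protocol

For *ns* cells and *nt* types, the step size *ss* is *ns* rounded to the
nearest hundred (ties up) divided by 100, and *h* runs from *ss* in
steps of *ss* to the smallest multiple of *ss* at or above
`0.5·ns/nt`; for each *h*, *q* ∈ {h, ⌊h/2⌋}, and ω sweeps
{0, 0.1, …, 1}. An explicit h-list override exists because published
grids occasionally truncate the rule's upper end. For every (h, q) the
best-over-ω value of each metric is recorded separately for ω = 0
(conventional) and ω > 0 (signed), and the two best-value lists, paired
by (h, q), are compared with a one-tailed Wilcoxon rank-sum test
(H₁: signed > conventional). The test follows the R `wilcox.test`
policy: exact tail enumeration P(W ≥ w) when the combined sample is
tie-free and ≤ 12 observations, otherwise a tie-corrected normal
approximation without continuity correction (identical samples then
give p = 0.5 exactly). An exceedance-proportion statistic (fraction of
grid points where the conventional variant meets or beats the signed
one) is reported alongside for transparency. Per-run k-means seeds are
derived as `seed + run_index`, so one integer reproduces an entire
sweep. Failed runs are recorded with an error marker, never dropped.

## Synthetic data

The generator plants *k* cell types with controllable rank-correlation
structure. On the log2 scale, cell *i* in cluster *c* has
`x_gi = μ_g + e_cg + ε_gi`: a shared gene baseline μ_g (variance *u*),
a cluster signature e_cg, and unit-variance cell noise. Signature genes
(half the genes by default) are organized in blocks arranged in a ring
over the clusters; each block is up-modulated in one cluster and
inverted in its ring partner, which is precisely the mechanism that
produces negative cross-type rank correlation — the structure the
dissimilarity matrix exists to detect. The split between *u* and the
per-block variance is solved in closed form from the requested
`within_corr` and `cross_corr`, so the generated data realizes those
targets approximately; cross-type targets too negative to be consistent
with the within-type target (u < 0) raise an error. Signature effects
have constant magnitude with random sign: Gaussian amplitudes would
concentrate the correlation in a few heavy-tailed genes, which Pearson
rewards but Spearman discounts.

TPM values are `2^x` with dropout: a value at within-cell expression
quantile *t* is zeroed with probability `3·d·(1 − t)²` (mean *d*,
default 0.3), mimicking the preferential dropout of low-expressed genes
in real protocols. Level-dependent dropout is also far less destructive
to rank structure than uniform Bernoulli zeroing, which is what lets
the generator hit its correlation targets in the presence of realistic
sparsity. The default fixture — 150 cells, 500 genes, three equal
types, within 0.6 / cross −0.2 targets, 30% dropout, seed 0 — is the
reference condition used by the tests and the acceptance script.

The companion QC simulator emits per-cell records where exactly
`n_fail` cells each violate one randomly chosen QC rule and all others
pass every rule with ≥ 10% margin, so filter outcomes are exact by
construction.

What the generator does **not** model: library-size variation, batch
effects, calibrated zero-inflation, gene-length bias, or continuous
differentiation trajectories. Passing tests on it demonstrate that the
pipeline's machinery is correct and that the signed construction
recovers planted anti-correlated structure; they do not predict
performance on any real dataset.

## Problem sizes and determinism

The test suite and the acceptance script run on the synthetic fixtures
above (40–150 cells, 150–500 genes; the acceptance sweep is 286 runs at
150 cells), sizes at which every linear-algebra step is dense and exact
and a full sweep completes in seconds. All randomness flows from
explicit integer seeds: the generator's `numpy` Generator, k-means'
`random_state`, and the sweep's derived per-run seeds.

## Known limitations

- The dense eigendecomposition scales as O(n³); beyond ~10⁴ cells a
  sparse reformulation would be needed (out of scope).
- The number of clusters *k* is an input, not estimated.
- Purity is reported but is not symmetric and saturates as the number
  of predicted clusters grows; rely on ARI/NMI for model comparison.
- With very weak planted structure, k-means on an indefinite-Laplacian
  embedding can occupy fewer than *k* clusters; this is surfaced as a
  warning naming the empty clusters.
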
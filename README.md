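# isclust

Signed-graph spectral clustering for identifying cell types in
single-cell RNA-seq data.

Conventional spectral clustering groups cells using only their
*similarities*: a nonnegative affinity graph is built, and cells are
embedded with the Laplacian's smallest eigenvectors. But scRNA-seq also
carries explicit *dissimilarity* information — pairs of cells whose gene
expression ranks move in opposite directions — and ignoring it discards
exactly the signal that separates distinct cell types. `isclust`
implements spectral clustering on a **signed incidence matrix** that
fuses both:

- Spearman's rank correlation ρ(i, j) across all genes measures each cell
  pair; the positive part is similarity *s(i, j)*, the negative part
  dissimilarity *ds(i, j)*.
- Each cell keeps its top-*h* positive partners and top-*q* most-negative
  partners (union-symmetrized k-nearest-neighbor rule), giving a sparse
  similarity matrix *S* ≥ 0 and dissimilarity matrix *DS* ≤ 0.
- The incidence matrix is the convex mix
  **W = (1 − ω) S + ω DS**, ω ∈ [0, 1]; ω = 0 recovers conventional
  spectral clustering, larger ω weights between-type repulsion more.
- With D′ = diag(row sums of W), the generalized Laplacian
  **L′ = D′ − W** (indefinite when ω > 0) is eigendecomposed; the rows of
  the matrix of its *k* algebraically smallest eigenvectors are the cell
  features, which k-means partitions into *k* clusters.

Clusterings are scored against reference labels with Purity, Rand index
(RI), adjusted Rand index (ARI) and normalized mutual information (NMI),
and a sweep driver explores the (ω, h, q) grid and compares the signed
variant against the conventional one with a one-tailed Wilcoxon rank-sum
test.

The package also ships the standard TPM preprocessing chain (cell-level
QC filtering, `log2(TPM+1)` transform with low-expression gene removal,
per-gene centering/scaling) and a planted-cluster synthetic generator so
the whole pipeline can be exercised without downloading any dataset.

## Worked example

Simulate three faint planted cell types (90 cells, 300 genes, mean
within-type Spearman target 0.08, cross-type −0.02, 60% dropout),
preprocess, and cluster with and without the dissimilarity term:

```sh
cat > spec.cfg <<EOF
n_cells = 90
n_genes = 300
k = 3
within_corr = 0.08
cross_corr = -0.02
dropout_rate = 0.6
seed = 5
EOF

isc simulate --spec spec.cfg -o expr.tsv --labels truth.tsv
isc preprocess --expr expr.tsv -o norm.tsv
isc run --expr norm.tsv --k 3 --omega 0.0 --h 12 --q 6 -o sc.tsv
isc metrics --pred sc.tsv --truth truth.tsv
isc run --expr norm.tsv --k 3 --omega 0.4 --h 12 --q 6 -o isc.tsv
isc metrics --pred isc.tsv --truth truth.tsv
```

which prints

```
{"purity": 0.988889, "ri": 0.985268, "ari": 0.966475, "nmi": 0.955321}
{"purity": 1.0, "ri": 1.0, "ari": 1.0, "nmi": 1.0}
```

At ω = 0 (conventional spectral clustering) one cell is misassigned;
mixing in the dissimilarity graph at ω = 0.4 recovers the planted
partition exactly — ARI rises from 0.966 to 1.0. The same workflow is
available as library calls (`simulate_expression`, `preprocess`,
`run_isc`, `evaluate`), and `isc sweep` scans the whole (ω, h, q) grid
and reports the best parameters per metric.

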
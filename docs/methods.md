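# Methods

This note documents the models, numerical conventions, and design
choices behind `scnrank`, and what the synthetic studies do and do not
establish about behaviour on real data.

## Pipeline model and assumptions

The pipeline assumes: (i) expression matrices are on the log₂ scale (a
`log2_transform` step with configurable offset is provided for raw
intensities); (ii) gene identifiers are case-sensitive symbols matched
exactly across expression, PPI, CRISPR and target inputs — no alias
resolution is attempted; (iii) the PPI is an undirected skeleton whose
confidence scores are only used for optional thresholding (`min_ppi_score`,
default 0 = keep all edges); (iv) correlations are estimated within one
expression context at a time (tumor-tissue columns for the tissue
network, cell-line columns for the cell-line network).

### Preprocessing

Probes with **more than** 20% missing entries are dropped (exactly 20%
is kept; the boundary is a strict inequality). Remaining gaps are filled
by K-nearest-neighbour imputation over probes (K = 10), with
nan-Euclidean distances — pairwise-complete Euclidean rescaled by the
fraction of shared observed columns — and a plain average of the
neighbours' values; observed cells are never modified, and K is clamped
(with a warning) when fewer neighbour rows exist. Probes mapping to the
same gene are averaged; unmapped probes are dropped and counted.
Quantile normalization forces every sample onto the row-wise mean of the
per-column sorted vectors, with ties receiving the mean of their
quantile values (average-rank convention); it is applied after the
probe→gene collapse. Note that quantile normalization assumes most genes
are not differentially expressed; a global one-directional shift is
partially absorbed into the reference distribution and attenuates fold
changes (this is visible in the synthetic studies and is a property of
the normalisation, not a bug).

CRISPR essentiality is a two-step mean: a gene's sgRNA fold changes are
averaged within each cell line, and those per-cell-line values are
averaged over the cell lines in which the gene was screened (a mean of
means, not a pooled guide mean — the two differ when guide counts vary
across cell lines).

### Differential expression

Per gene, an unpaired two-sided t-test between tumor and normal samples;
the default variant is Welch (unequal variances), motivated by unequal
group sizes, with Student's pooled-variance test available. `log_fc` is
defined strictly as the difference of log₂ group means. Selection keeps
genes with raw p < α (default 0.05) **and** log_fc > 0. No
multiple-testing correction is applied by default, matching the
published procedure; a Benjamini–Hochberg option exists but is off. Two
zero-variance groups with equal means return (t = 0, p = 1) rather than
NaN.

### The fold-change-weighted Laplacian

With S′ the signed correlation matrix restricted to the PPI skeleton
(r_aa = 1 on the diagonal, 0 where no edge) and FC the positive node
weights, the construction is

    S″_ab = r_ab · FC_a / Σ_k r_ak      (row sums include the diagonal)
    L_raw = diag(FC) − S″
    L     = diag(FC)^(−1/2) · L_raw · diag(FC)^(−1/2)

Numerical conventions:

- **Diagonal convention.** The unit diagonal is included in both S′ and
  the row sums. In the binary-correlation limit with FC_a set to the
  affinity row sum Σ_k S′_ak (= degree + 1), S″ = S′ and
  L_raw = (D + I) − (A + I) = D − A — the ordinary graph Laplacian,
  exactly. The construction is therefore a strict generalisation of
  standard spectral clustering.
- **Signed correlations** enter S′ as-is (not absolute values). Rows
  whose correlation sum is within ε = 1e−8 of zero are zeroed with a
  warning, and diag(FC) entries are floored at ε before the −1/2 power.
- **Symmetrisation.** Row normalisation by FC_a/Σ_k r_ak makes L
  slightly asymmetric when fold changes are heterogeneous; the
  eigenproblem uses (L + Lᵀ)/2 so eigenpairs are real, and the maximum
  asymmetry is retained as a diagnostic on the matrices object.
- **Determinism.** Eigenvectors are sorted by eigenvalue ascending and
  sign-fixed by forcing each vector's largest-magnitude entry positive.
- Isolated nodes are retained: their L row is zero, so they contribute
  an extra (near-)zero eigenvalue, exactly as a singleton connected
  component does in the standard theory.

### Choosing K

Hartigan's number H(k) = (W_k/W_{k+1} − 1)(n − k − 1), with W_k the
best-of-restarts K-means within-cluster sum of squares, is scanned from
k = 1; the first k with H(k) < 10 is selected (k_max with a warning if
none qualifies). W_k = 0 yields H = 0 (so identical points give K = 1).

Two practical notes. First, the scan needs an embedding whose dimension
roughly matches the structure: eigenvectors are orthonormal, so every
noise dimension adds ~1 unit of within-SS that K-means cannot remove,
flattening the W_k ratios. The auto-K path therefore sizes the scan
embedding by the eigengap (largest gap among the smallest eigenvalues,
capped at 40) and runs the Hartigan scan inside it; the eigenvector
count m for the final clustering defaults to min(K, 40) and is an
independent knob. Second, the (n − k − 1) factor means the 10-rule keeps
splitting while relative improvements exceed ≈ 10/n — on thousands of
genes it produces hundreds of clusters by design, and on small synthetic
embeddings it only stops cleanly for blobs of a few dozen points. Both
behaviours are inherent to the published rule, which also does not
guarantee a global optimum.

"Top K eigenvalues" is interpreted as the K **smallest** eigenvalues of
the normalized Laplacian (the standard relaxation); `eigen_order =
"largest"` is available for comparison experiments.

K-means uses k-means++ with 10 restarts under a fixed, recorded seed.
Cluster labels are compacted to 0..K−1; if K-means returns fewer
non-empty clusters than requested (duplicate embedding points), the
actual count is reported with a warning.

### Target Influence

The "most correlated path" between a target and a cluster gene maximises
the absolute product of edge correlations. Since |r| ≤ 1, edge costs
−log|r| are non-negative and Dijkstra minimising the cost sum maximises
∏|r|; the signed product along the returned path is reported. A
reciprocal-cost mode (1/|r|) is retained behind `path_mode` for
comparison — it favours few strong hops but does not optimise the
product, so the log-cost form is the default. Zero-weight edges are
removed before the search (−log 0 undefined); genes with essentiality 0
contribute nothing to TI but still relay paths. The search is restricted
to the subgraph induced by the target's cluster, so TI is invariant to
any edit outside it.

TI sums node weight × signed best-path product over all reachable
cluster genes, the target itself included with product 1. Ranking is by
|TI| descending with lexicographic tie-break; the per-cluster
representative is the cluster's top-|TI| target. Because essentiality
values are predominantly negative, strong targets have large negative
TI; magnitude ranking reflects that while the signed value is always
reported.

## Synthetic studies

The generator emulates the statistical structure the pipeline assumes:

- **Expression** follows a one-factor-per-block Gaussian model: within a
  block, gene = baseline + effect + scale·(λ·factor_s + ε), with λ =
  √(r/(1−r)) so the expected within-block correlation is exactly the
  `intra_block_r` knob (closed form r = λ²/(λ² + 1)), and `scale` chosen
  so every gene's within-group sd equals `expression_sd`. Defaults:
  200 genes, four 20-gene blocks, 40/40/40 tumor/normal/cell-line
  samples, effect size 1.0 log₂ units, intra-block r 0.7, expression sd
  0.5 log₂ units — a realistic spread for log-scale microarray data, and
  a differentially-expressed fraction (40%) of the same order as large
  tumor/normal comparisons. Tumor and cell-line samples carry the block
  shift; normal samples do not.
- **PPI**: every within-block pair at score 900 plus Bernoulli(0.05)
  cross-block noise edges at score 400.
- **CRISPR**: one planted hub per block with essentiality −2.0 (small
  jitter keeps hub magnitudes distinct) against a N(−0.2, 0.3²)
  background; 4 sgRNAs per gene in each of 5 cell lines with N(0, 0.2²)
  guide noise.
- **Targets**: the hubs plus 3 random non-hub block genes per block.
- 5% of cells are masked missing; everything derives from one seed.

What passing on this generator does **not** show: robustness to
heavy-tailed intensities, batch structure, probe-level artefacts,
many-to-one probe maps at scale, identifier mismatches, PPI false-edge
structure beyond uniform noise, or cell-line heterogeneity in CRISPR
response. Between-block sample correlations fluctuate as a whole
(they share one factor-pair realisation per context), so checks on them
need enough samples to be sharp.

Problem sizes used in the test and acceptance runs — 200-gene studies,
20 seeds, ≤ 8-node graphs for the exhaustive path oracle (200 graphs),
16-node Laplacian-limit graphs, 12-point Hartigan blobs — are desk-scale
choices that keep every statistical check sharp while the full suite
runs in well under a minute.

## Known limitations

- The raw p < 0.05 selection (no FDR control) follows the published
  procedure and inflates the selected set by construction; the BH option
  is provided for users who want control.
- Hartigan's 10-rule over-partitions large networks (see above); K can
  be fixed explicitly.
- The weighted Laplacian requires strictly positive node weights, which
  confines clustering to the tissue (over-expressed) context.
- TI is a within-cluster score; influence across cluster boundaries is
  deliberately zero, so cluster granularity shapes the ranking.
- Negative correlation rows sums near zero are zeroed rather than
  rescaled, which can disconnect a node from the embedding; the case is
  logged when it occurs.
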
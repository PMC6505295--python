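# Methods

## Random walk with restart

Propagation smooths each cell's expression vector over a gene graph. With
adjacency *B* and diagonal degree matrix *D*, the transition matrix is
*W* = *BD*⁻¹, normalized by **column** so that every column of *W* sums to
one (columns of isolated genes stay all-zero and are logged). The update
is applied in the column-vector convention, p ← r p₀ + (1 − r) W p. With a
row-vector convention and the same normalization the walk would not
conserve mass, so the column form is the one implemented; per-cell totals
are conserved exactly (to 1e-8) whenever every measured gene sits in a
connected component of the network.

Two solvers produce the same steady state:

- *closed form* — one LU factorization of I − (1 − r)W, reused as a
  multi-right-hand-side solve across all cells. Default for networks up
  to 5000 nodes, where the single factorization amortizes well.
- *iterative* — power-style iteration with an L1 stopping rule
  (tol 1e-6, max 1000 iterations; non-convergence raises with the last
  residual rather than returning a half-converged matrix).

The two agree to better than 1e-6 on random graphs up to 200 nodes; the
acceptance script re-measures the worst observed discrepancy at run time.

Restart probability `r` defaults to 0.5. `r = 1` returns the input
unchanged; `r = 0` is rejected, because the steady state would then be
the walk's stationary distribution and ignore the cell entirely.

Genes present in the expression matrix but absent from the network pass
through unchanged — smoothing never destroys measured signal it cannot
place on the graph. Network genes absent from the matrix participate in
the walk with zero initial mass; whatever mass diffuses into them is
logged and dropped rather than invented as new rows. The optional
`rescale` flag restores each cell's original total over the measured gene
block, compensating for that leak; it is off by default since downstream
normalization is usually the caller's choice.

## Network sources

**Priori mode** takes a weighted edge list (duplicate edges keep the
maximum weight; self-loops are dropped). Edges below the `edge_quantile`
sample quantile (linear interpolation; default 0.90, i.e. top 10% of
edges by score) are removed, with ties at the threshold kept for
determinism, and genes left without neighbours are pruned. Note the
operation is defined relative to the current edge-weight distribution, so
re-applying it with the same quantile prunes further unless the weights
are tied; it is a one-shot reduction, not a projection.

**Context mode** learns the network from the data:

1. log2(x + 1) transform of the counts;
2. drop genes whose *total* transformed expression falls below the
   `gene_expr_percentile` quantile (default 0.60). "Summarized
   expression" is interpreted as the per-gene sum, the usual
   total-expression reading in weighted-correlation-network practice;
3. the analogous cell filter at the 0.50 quantile, skipped entirely when
   the data has fewer than 30 cells (tiny data sets cannot spare half
   their cells);
4. drop genes/cells with more than 95% zeros and genes with zero
   variance — a deliberately explicit two-rule reduction of the usual
   iterative good-samples heuristic, chosen so the filter is
   deterministic and fully specified;
5. unsigned adjacency a_ij = |pearson_cor|^p with soft power p = 6 (the
   standard unsigned-network default; exposed as configuration along with
   the filters above) and the topological overlap matrix
   TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
   l_ij = Σ_u a_iu a_uj, k_i = Σ_u a_iu.

The full dense TOM (diagonal zeroed) is used as the propagation network;
no thresholding is applied before the walk, since the walk itself
discounts weak edges through degree normalization. The edge-list exporter
accepts a minimum-weight cutoff purely to bound file size.

The counts propagated in context mode are the original (untransformed)
values; the log transform exists only to estimate correlations.

## Fusion

Affinities use the scaled exponential kernel
W_ij = exp(−d_ij² / (β α_ij)) on Euclidean distances between cell
profiles, with α_ij = (mean distance of i to its K nearest neighbours +
the same for j + d_ij)/3. α is floored at 1e-12 (with a warning) when
duplicate-heavy data collapses it to zero. Distances are computed on the
matrices exactly as provided — the fusion step is transform-agnostic, and
callers decide whether to log-transform first.

From W: the full kernel P row-normalizes the off-diagonal to total 1/2
with diagonal exactly 1/2; the sparse kernel S row-normalizes over each
cell's neighbourhood, defined as the cell itself plus its K most similar
other cells (|N_i| = K + 1, keeping K the count of true neighbours).
K-nearest ties break by lexicographic cell id for determinism. A cell
with no off-diagonal affinity gets a point-mass row, with a warning.

Cross-diffusion runs T iterations of P^a ← S^a · mean(P^others) · (S^a)ᵀ
(the mean-of-others form generalizes the two-view update to m views).
After every iteration each status matrix is renormalized back to the
full-kernel form (off-diagonal 1/2, diagonal 1/2); the bare update is not
trace-preserving and drifts without this step, so the renormalization is
an explicit, test-covered stabilization rather than part of the update
equation. The fused output is the mean of the final status matrices,
symmetrized. T = 0 degenerates to the mean of the initial full kernels.

Defaults K = 20, β = 0.5, T = 10; the test suite checks that the fused
output stays symmetric, finite and nonnegative — and that clustering
accuracy on the synthetic fixture moves by less than 0.1 ARI — across
K ∈ {10, 15, 20}, β ∈ {0.3, 0.5, 0.8}, T ∈ {10, 20}.

## Clustering and metrics

- k-means clusters the similarity rows as feature vectors (seeded,
  10 initializations); spectral clustering embeds the similarity as an
  affinity via the normalized Laplacian and k-means in the embedding;
  hierarchical (average linkage) and PAM operate on the dissimilarity
  max(sim) − sim. PAM is the classic BUILD + SWAP algorithm and is fully
  deterministic, so its seed argument is accepted for interface symmetry
  but unused.
- ARI is the Hubert–Arabie adjusted Rand index; Jaccard counts pairs
  co-clustered in both partitions over pairs co-clustered in either;
  purity averages each cluster's majority-class fraction; NMI defaults to
  the geometric-mean normalization (min and max are available). When both
  partitions are a single identical class, all four metrics are 1 by
  convention (the 0/0 entropy case), with a warning.
- Davies–Bouldin uses Euclidean centroids and mean member-to-centroid
  scatter; zero-scatter (singleton) clusters contribute zero ratios, so
  an all-singleton clustering scores 0. Dunn is the minimum
  between-cluster point distance over the maximum within-cluster
  diameter, +inf (with a warning) when every cluster is a singleton.
  Connectivity sums reciprocal ranks 1/j over each observation's L = 10
  nearest neighbours that land in a different cluster. Internal metrics
  are computed on the representation handed to them — for
  similarity-based clustering, the similarity rows, i.e. the same
  representation k-means clusters.
- The evaluation harness repeats clustering with consecutive seeds and
  reports per-run metrics plus medians, since single k-means runs are not
  informative about a similarity matrix's quality.

## Synthetic data

The generator emulates the regime this kind of preprocessing targets: a
sparse count matrix in which most entries are zero and cluster identity
is carried by modules of co-regulated genes.

- Baseline per-gene means are log-normal (meanlog 1.0, sdlog 1.0 —
  mostly low-expressed genes with a heavy right tail).
- 60% of genes belong to one of `n_modules` modules (round-robin); module
  m's genes are upregulated by 2^de_strength (default 4-fold, the scale
  of separation expected between distinct cell types) in cluster
  m mod n_clusters. The remaining 40% are unstructured background.
- Counts are negative-binomial with dispersion 0.3 (variance μ + 0.3 μ²).
- Dropout zeroes each positive entry with probability
  exp(−λ log(1 + μ/dropout_mid)²) — monotone in expression, so lowly
  expressed genes drop out more. λ is calibrated by bisection on the
  expected zero fraction given the realized counts, so the overall zero
  fraction hits `dropout_rate_target` within ±0.03. If the
  negative-binomial zeros already exceed the target, no additional
  dropout is applied (with a warning). Everything is deterministic given
  the seed.
- Cluster sizes are balanced by default; `cluster_props` is the
  imbalance knob.
- The companion network generator plants the same modules as dense
  communities (edge probability 0.8, weights near `intra_weight`) over a
  sparse background (probability 0.02, weights near `inter_weight`) and
  guarantees connectivity by bridging components with weak edges.

The default fixture is 300 genes × 150 cells, 3 clusters, ~70% zeros —
sizes at which the whole pipeline runs in about a second, so properties
can be checked over ten seeds routinely.

What the generator does **not** emulate: library-size variation between
cells, batch effects, trajectories/continuous states, gene–gene
correlation beyond the planted block structure, and the zero-inflation
patterns of any specific protocol. Passing tests therefore demonstrate
that the algorithms behave as specified and recover planted structure
under heavy dropout — not that any particular accuracy carries over to a
given real data set.

A note on scale: on this fixture, spectral clustering of a raw-scale
Euclidean affinity of the counts fails (ARI ≈ 0, distances dominated by
a few high-expression genes), while the fused similarity recovers the
planted clusters exactly; after a log transform the single views also
cluster perfectly. The acceptance script reports the raw-scale route for
both the fused and the per-view numbers so the comparison is like for
like.

## Numerical choices

- Quantile filters use numpy's linear-interpolation sample quantile;
  entries exactly at a threshold are kept.
- GeneNetwork construction checks symmetry to 1e-12 and then symmetrizes
  exactly; similarity matrices check to 1e-8. TOM output is clipped to
  [0, 1] against round-off.
- Transition-matrix columns must sum to 1 within 1e-10 or be all-zero.
- Kernel row-sum contracts (P and S rows sum to 1 within 1e-10) are
  enforced by construction and re-checked in tests after every fusion
  iteration.
- Degenerate inputs fail loudly: empty matrices after QC, empty gene
  intersection between matrix and network, k ≥ n_cells, single-cluster
  inputs to internal metrics.

## Interface shape

The three pipeline stages are exposed as scikit-learn-style estimators
(`NetworkPropagation` fit/transform, `SimilarityFusion` fit/fit_transform,
`SimilarityClusterer` fit/fit_predict) operating on the package's domain
containers, with plain functions (`scnpf_propagation`, `snf_fuse`,
`cluster_similarity`, ...) as thin wrappers; the `scnpf` command-line
tool is a thin layer over those functions.
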
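# scnpf

Network-propagation and network-fusion preprocessing for single-cell
RNA-seq expression matrices.

Single-cell RNA-seq counts are extremely sparse: a large fraction of
entries — often 85–95% — are zero, many of them *dropouts* (genes that are
expressed but not captured). Downstream analyses such as cell-type
clustering operate on the gene–cell matrix, so this package smooths it
before analysis by diffusing each cell's expression profile over a
gene–gene network, then learns a single cell–cell similarity matrix by
fusing several smoothed views of the same cells.

It is aimed at computational biologists preparing sparse count matrices
for clustering, dimension reduction or visualization, and at method
developers who need a seeded, fully synthetic test bed for
network-based imputation.

## The model

**Propagation.** Given a weighted undirected gene network with adjacency
*B*, form the column-stochastic transition matrix *W* = *BD*⁻¹ (with *D*
the diagonal degree matrix). Each cell's profile *p*₀ is smoothed by a
random walk with restart:

    p_{t+1} = r p₀ + (1 − r) W p_t

which converges to the steady state *p* = *r* (*I* − (1 − *r*)*W*)⁻¹ *p*₀.
The restart probability *r* ∈ (0, 1] trades the measured profile against
network diffusion (*r* = 1 means no smoothing; default *r* = 0.5). Two
network sources are supported:

- **priori mode** — a public interaction network (e.g. a STRING-style
  edge list), reduced to its top-scoring edges;
- **context mode** — a co-expression network learned from the data itself:
  unsigned adjacency *a*ᵢⱼ = |cor(*g*ᵢ, *g*ⱼ)|^*p* on log-transformed,
  abundance-filtered counts, combined into the topological overlap matrix
  TOMᵢⱼ = (*l*ᵢⱼ + *a*ᵢⱼ) / (min(*k*ᵢ, *k*ⱼ) + 1 − *a*ᵢⱼ).

**Fusion.** For each smoothed matrix a cell affinity
*W*ᵢⱼ = exp(−*d*ᵢⱼ² / (*β* *α*ᵢⱼ)) is built from Euclidean distances with a
locally adaptive scale *α*. Two kernels follow: the full kernel *P* (rows
sum to 1, diagonal 1/2) and the sparse *K*-nearest-neighbour kernel *S*.
Cross-diffusion *P*ᵃ ← *S*ᵃ *P*ᵇ (*S*ᵃ)ᵀ for *T* iterations reinforces
similarities supported by both views; the fused similarity is the mean of
the final status matrices. Defaults: *K* = 20, *β* = 0.5, *T* = 10.

**Evaluation.** Four clustering front-ends (k-means on similarity rows,
spectral, average-linkage hierarchical, PAM) and seven metrics: ARI,
pair-counting Jaccard, purity and NMI against known labels;
Davies–Bouldin, Dunn and connectivity without labels.

## Worked example

Simulate a labelled fixture (300 genes × 150 cells, 3 cell clusters,
~70% zeros), smooth it in both modes, fuse, and evaluate:

```bash
scnpf simulate --genes 300 --cells 150 --clusters 3 --dropout 0.7 --seed 1 --out fixture/
scnpf propagate --expr fixture/expression.mtx --mode context --out context.mtx
scnpf propagate --expr fixture/expression.mtx --mode priori \
      --network fixture/network.tsv --out priori.mtx
scnpf fuse --inputs context.mtx,priori.mtx --K 20 --beta 0.5 --T 10 --out fused.tsv
scnpf evaluate --sim fused.tsv --labels fixture/labels.tsv --k 3 \
      --method spectral --runs 10 --seed 1000 --report report.json
```

prints

```
wrote fixture to fixture (zero fraction 0.701)
propagated 300 genes x 150 cells (zero fraction 0.701 -> 0.504)
propagated 300 genes x 150 cells (zero fraction 0.701 -> 0.314)
fused 2 views over 150 cells -> fused.tsv
{
  "connectivity": 93.94047619047643,
  "dbi": 5.870178448345288,
  "dunn": 0.6768716619984099,
  "ari": 1.0,
  "jaccard": 1.0,
  "purity": 1.0,
  "nmi": 1.0
}
```

Propagation fills dropout zeros (70% → 50% zeros in context mode, → 31%
in priori mode, whose network covers every gene), and spectral clustering
of the fused similarity recovers the three planted cell types exactly
(ARI = 1) in all ten runs — the median of each metric is reported.

The same pipeline is available as a library of scikit-learn-style
estimators:

```python
from scnpf import (NetworkPropagation, SimilarityFusion, SimilarityClusterer,
                   SimulationConfig, simulate_expression, simulate_network)

expr, labels, modules = simulate_expression(SimulationConfig(seed=1))
net = simulate_network(modules, seed=1, gene_ids=expr.gene_ids)

ctx = NetworkPropagation(mode="context").fit(expr).transform(expr)
pri = NetworkPropagation(mode="priori", network=net).fit(expr).transform(expr)
fused = SimilarityFusion(K=20, beta=0.5, T=10).fit_transform([ctx, pri])
pred = SimilarityClusterer(n_clusters=3, method="spectral").fit_predict(fused)
```

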
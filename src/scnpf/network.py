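"""Construction of the gene-gene network used for propagation.

Two sources are supported. A *priori* network comes from a public
interaction database and is reduced to its strongest edges (top quantile by
confidence score, then zero-degree genes pruned). A *context* network is
learned from the expression data itself: log-transformed counts are
filtered for low-abundance genes/cells, an unsigned weighted correlation
adjacency ``a_ij = |cor(g_i, g_j)|^p`` is raised to a soft-thresholding
power ``p``, and the topological overlap matrix (TOM)

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj,  k_i = sum_u a_iu

combines direct adjacency with shared-neighbour structure. The dense TOM,
with its diagonal removed, is the context network's adjacency.

Expression QC (mean cutoff + minimum expressing cells) lives here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ContextNetworkConfig",
    "PrioriNetworkConfig",
    "qc_filter_genes",
    "prepare_priori_network",
    "context_preprocess",
    "tom_adjacency",
]


@dataclass
class ContextNetworkConfig:
    """Settings for building the context-specific co-expression network.

    soft_power
        Exponent applied to |Pearson correlation| (unsigned adjacency).
    gene_expr_percentile
        Genes whose total transformed expression falls below this sample
        quantile are dropped (default 0.60: keep above the 60th percentile).
    cell_expr_percentile
        Same for cells (default 0.50), skipped entirely when the data has
        fewer than ``min_cells_for_cell_filter`` cells.
    missing_fraction_max
        Genes or cells with a larger fraction of zero entries are dropped.
    """

    soft_power: int = 6
    gene_expr_percentile: float = 0.60
    cell_expr_percentile: float = 0.50
    min_cells_for_cell_filter: int = 30
    missing_fraction_max: float = 0.95

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        for name in ("gene_expr_percentile", "cell_expr_percentile"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 < self.missing_fraction_max <= 1:
            raise ValueError("missing_fraction_max must be in (0, 1]")
        if self.min_cells_for_cell_filter < 1:
            raise ValueError("min_cells_for_cell_filter must be positive")


@dataclass
class PrioriNetworkConfig:
    """Settings for reducing a public interaction network.

    edge_quantile
        Keep edges whose weight is at or above this sample quantile of all
        edge weights (default 0.90: the top 10% of edges by score).
    drop_zero_degree
        Remove genes left with zero weighted degree after edge filtering.
    """

    edge_quantile: float = 0.90
    drop_zero_degree: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.edge_quantile < 1:
            raise ValueError("edge_quantile must be in [0, 1)")


def qc_filter_genes(
    expr: ExpressionMatrix, mean_cutoff: float = 0.01, min_cells: int = 3
) -> ExpressionMatrix:
    """Drop low-abundance genes before any downstream processing.

    A gene survives when its mean expression across cells is at least
    ``mean_cutoff`` and it is detected (value > 0) in at least ``min_cells``
    cells. Cells and the order of surviving genes are untouched.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    means = expr.values.mean(axis=1)
    n_expressed = (expr.values > 0).sum(axis=1)
    keep = (means >= mean_cutoff) & (n_expressed >= min_cells)
    if not keep.any():
        raise ValueError("empty after QC: no gene passes the mean/min-cells filter")
    return expr.subset_genes(keep)


def prepare_priori_network(
    net: GeneNetwork, cfg: PrioriNetworkConfig | None = None
) -> GeneNetwork:
    """Reduce a priori network to its strongest edges.

    Edges below the ``edge_quantile`` sample quantile (linear interpolation)
    of all edge weights are removed; ties at the threshold are kept. Genes
    whose summed neighbour score drops to zero are then pruned.
    """
    cfg = cfg or PrioriNetworkConfig()
    adj = net.adjacency.copy()
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    weights = adj[iu, ju]
    weights = weights[weights > 0]
    if weights.size == 0:
        raise ValueError("priori network has no edges")
    threshold = float(np.quantile(weights, cfg.edge_quantile))
    adj[adj < threshold] = 0.0
    out = GeneNetwork(list(net.node_ids), adj)
    if cfg.drop_zero_degree:
        keep = out.degrees() > 0
        if not keep.any():
            raise ValueError("empty network after edge filtering")
        ids = [g for g, k in zip(out.node_ids, keep) if k]
        out = out.subnetwork(ids)
    return out


def context_preprocess(
    expr: ExpressionMatrix, cfg: ContextNetworkConfig | None = None
) -> ExpressionMatrix:
    """Prepare raw counts for co-expression network construction.

    Applies, in order: log2(x+1); removal of genes below the
    ``gene_expr_percentile`` quantile of per-gene total expression (ties at
    the threshold kept); removal of cells below the ``cell_expr_percentile``
    quantile of per-cell totals, skipped for small data sets
    (< ``min_cells_for_cell_filter`` cells); removal of genes and cells
    with too many zero entries; removal of zero-variance genes.
    """
    cfg = cfg or ContextNetworkConfig()
    log = ExpressionMatrix(
        np.log2(expr.values + 1.0), list(expr.gene_ids), list(expr.cell_ids)
    )

    gene_totals = log.values.sum(axis=1)
    thr = np.quantile(gene_totals, cfg.gene_expr_percentile)
    log = log.subset_genes(gene_totals >= thr)
    if log.n_genes == 0:
        raise ValueError("empty after gene abundance filter")

    if log.n_cells >= cfg.min_cells_for_cell_filter:
        cell_totals = log.values.sum(axis=0)
        thr = np.quantile(cell_totals, cfg.cell_expr_percentile)
        log = log.subset_cells(cell_totals >= thr)
        if log.n_cells == 0:
            raise ValueError("empty after cell abundance filter")

    gene_zero_frac = (log.values == 0).mean(axis=1)
    log = log.subset_genes(gene_zero_frac <= cfg.missing_fraction_max)
    if log.n_genes:
        cell_zero_frac = (log.values == 0).mean(axis=0)
        log = log.subset_cells(cell_zero_frac <= cfg.missing_fraction_max)
    if log.n_genes and log.n_cells:
        log = log.subset_genes(log.values.var(axis=1) > 0)
    if log.n_genes == 0 or log.n_cells == 0:
        raise ValueError("empty after missing-entry / zero-variance filters")
    return log


def tom_adjacency(expr_pre: ExpressionMatrix, soft_power: int = 6) -> GeneNetwork:
    """Topological overlap network from preprocessed expression data.

    ``a_ij = |pearson_cor(gene_i, gene_j)|^soft_power`` with zero diagonal;
    the TOM combines the direct adjacency with one-step shared-neighbour
    connectivity and lies in [0, 1]. The returned network is the TOM with
    its diagonal zeroed.
    """
    if expr_pre.n_genes < 3 or expr_pre.n_cells < 3:
        raise ValueError("TOM construction needs at least 3 genes and 3 cells")
    sd = expr_pre.values.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr_pre.gene_ids, sd) if s == 0]
        raise ValueError(
            f"zero-variance genes must be filtered before TOM: {bad[:5]}"
        )
    cor = np.corrcoef(expr_pre.values)
    a = np.abs(cor) ** soft_power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 0.0)
    return GeneNetwork(list(expr_pre.gene_ids), tom)
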
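"""Synthetic scRNA-seq counts with planted cell clusters, planted gene
co-expression modules, and calibrated dropout, plus matching toy gene
networks.

The generator emulates the regime network-propagation preprocessing
targets: a sparse negative-binomial count matrix in which most entries are
zero (dropout plus genuinely silent genes) and in which cluster identity is
carried by modules of co-regulated marker genes. Dropout is expression-
dependent (low expressors drop out more) through the curve

    P(drop | mu) = exp(-lambda * log(1 + mu)^2)

with lambda calibrated by bisection so the realized overall zero fraction
matches a requested target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse.csgraph

from .containers import ExpressionMatrix, GeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "simulate_expression", "simulate_network"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    n_genes, n_cells, n_clusters, n_modules
        Matrix size, planted cell clusters, planted gene modules (each
        module is the marker set of one cluster, round-robin).
    module_gene_fraction
        Fraction of genes assigned to modules; the rest are unstructured
        background (module label -1).
    de_strength
        log2 fold-change of a module's genes in its marked cluster.
    nb_dispersion
        Negative-binomial dispersion phi (variance mu + phi mu^2).
    base_mean_log, base_mean_sd
        Log-normal parameters of per-gene baseline means.
    dropout_mid
        Scale of the dropout curve's expression axis (mu is divided by it).
    dropout_rate_target
        Overall zero fraction to calibrate towards (0 disables dropout).
    cluster_props
        Optional per-cluster proportions; balanced when None.
    """

    n_genes: int = 300
    n_cells: int = 150
    n_clusters: int = 3
    n_modules: int = 3
    module_gene_fraction: float = 0.6
    de_strength: float = 2.0
    nb_dispersion: float = 0.3
    base_mean_log: float = 1.0
    base_mean_sd: float = 1.0
    dropout_mid: float = 1.0
    dropout_rate_target: float = 0.7
    seed: int = 0
    cluster_props: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_cells:
            raise ValueError("n_clusters cannot exceed n_cells")
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules cannot exceed n_genes")
        if not 0 <= self.dropout_rate_target < 1:
            raise ValueError("dropout_rate_target must be in [0, 1)")
        for name in ("de_strength", "nb_dispersion", "dropout_mid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.module_gene_fraction <= 1:
            raise ValueError("module_gene_fraction must be in (0, 1]")


def _cluster_labels(cfg: SimulationConfig) -> np.ndarray:
    if cfg.cluster_props is None:
        props = np.full(cfg.n_clusters, 1.0 / cfg.n_clusters)
    else:
        props = np.asarray(cfg.cluster_props, dtype=float)
        if props.size != cfg.n_clusters or np.any(props <= 0):
            raise ValueError("cluster_props must be n_clusters positive fractions")
        props = props / props.sum()
    counts = np.floor(props * cfg.n_cells).astype(int)
    counts[: cfg.n_cells - counts.sum()] += 1
    return np.repeat(np.arange(cfg.n_clusters), counts)


def _module_map(cfg: SimulationConfig) -> np.ndarray:
    n_module_genes = max(cfg.n_modules, int(round(cfg.module_gene_fraction * cfg.n_genes)))
    n_module_genes = min(n_module_genes, cfg.n_genes)
    modules = np.full(cfg.n_genes, -1, dtype=int)
    modules[:n_module_genes] = np.arange(n_module_genes) % cfg.n_modules
    return modules


def _dropout_lambda(counts: np.ndarray, mu: np.ndarray, cfg: SimulationConfig) -> float | None:
    """Bisect lambda so the expected overall zero fraction hits the target.

    The expected zero fraction given realized counts is
    mean(1{count==0} + 1{count>0} * P(drop|mu)), monotone decreasing in
    lambda. Returns None when no additional dropout is needed.
    """
    nb_zero = float(np.mean(counts == 0))
    target = cfg.dropout_rate_target
    if target <= nb_zero:
        if target > 0:
            logger.warning(
                "dropout target %.2f already exceeded by count zeros (%.2f); "
                "no additional dropout applied",
                target,
                nb_zero,
            )
        return None
    logmu2 = np.log1p(mu / cfg.dropout_mid) ** 2

    def zero_frac(lam: float) -> float:
        p = np.exp(-lam * logmu2)
        return float(np.mean(np.where(counts == 0, 1.0, p)))

    lo, hi = 0.0, 1.0
    while zero_frac(hi) > target:
        hi *= 2.0
        if hi > 1e6:
            break
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if zero_frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Generate a labelled count matrix with planted structure.

    Returns ``(expr, labels, modules)``: the genes x cells count matrix,
    balanced per-cell cluster labels, and the per-gene module assignment
    (-1 for background genes). Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = _cluster_labels(cfg)
    modules = _module_map(cfg)

    base = rng.lognormal(cfg.base_mean_log, cfg.base_mean_sd, size=cfg.n_genes)
    mu = np.tile(base[:, None], (1, cfg.n_cells))
    for m in range(cfg.n_modules):  # module m marks cluster m mod C
        gene_mask = modules == m
        if gene_mask.any():
            cell_mask = labels == (m % cfg.n_clusters)
            mu[np.ix_(gene_mask, cell_mask)] *= 2.0**cfg.de_strength

    size = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(float)

    if cfg.dropout_rate_target > 0:
        lam = _dropout_lambda(counts, mu, cfg)
        if lam is not None:
            p_drop = np.exp(-lam * np.log1p(mu / cfg.dropout_mid) ** 2)
            counts[rng.random(counts.shape) < p_drop] = 0.0

    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    cell_ids = [f"c{i:04d}" for i in range(cfg.n_cells)]
    return ExpressionMatrix(counts, gene_ids, cell_ids), labels, modules


def simulate_network(
    module_map: np.ndarray,
    intra_weight: float = 1.0,
    inter_weight: float = 0.1,
    seed: int = 0,
    p_intra: float = 0.8,
    p_inter: float = 0.02,
    gene_ids: list[str] | None = None,
    ensure_connected: bool = True,
) -> GeneNetwork:
    """Planted-partition gene network matching a module assignment.

    Genes sharing a module (label >= 0) are densely connected with weights
    near ``intra_weight``; all other pairs (including background genes,
    label -1) connect sparsely with weights near ``inter_weight``. A
    minimal set of weak bridging edges then connects any remaining
    components (skipped when ``ensure_connected`` is False).
    """
    module_map = np.asarray(module_map)
    if inter_weight >= intra_weight or inter_weight < 0:
        raise ValueError("need intra_weight > inter_weight >= 0")
    n = module_map.size
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    same = (module_map[iu] == module_map[ju]) & (module_map[iu] >= 0)
    u = rng.random(iu.size)
    jitter = rng.uniform(0.5, 1.0, size=iu.size)
    w = np.zeros(iu.size)
    w[same & (u < p_intra)] = intra_weight
    if inter_weight > 0:
        w[~same & (u < p_inter)] = inter_weight
    w *= jitter
    adj[iu, ju] = w
    adj[ju, iu] = w

    if ensure_connected:
        n_comp, comp = scipy.sparse.csgraph.connected_components(
            scipy.sparse.csr_matrix(adj > 0), directed=False
        )
        if n_comp > 1:
            weak = inter_weight if inter_weight > 0 else 0.01 * intra_weight
            reps = [int(np.argmax(comp == c)) for c in range(n_comp)]
            for a, b in zip(reps[:-1], reps[1:]):
                adj[a, b] = adj[b, a] = weak
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n)]
    return GeneNetwork(list(gene_ids), adj)
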
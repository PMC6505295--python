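"""Similarity network fusion: one cell-cell similarity from several views.

For each input expression matrix (a "view": e.g. a context-propagated and a
priori-propagated matrix over the same cells) a cell affinity is built with
the scaled exponential kernel

    W_ij = exp(-d_ij^2 / (beta * alpha_ij)),
    alpha_ij = (mean_knn_dist_i + mean_knn_dist_j + d_ij) / 3

where d is the Euclidean distance between cell profiles and alpha adapts
the bandwidth to local scale. From W two kernels are derived: the full
kernel P (off-diagonal rows normalized to total 1/2, diagonal exactly 1/2)
carrying global similarity, and the sparse kernel S (row-normalized over
each cell's K-nearest neighbourhood including itself, zero elsewhere)
carrying only local structure. Cross-diffusion then iterates

    P^a <- S^a x mean(P^others) x (S^a)^T

for T steps, letting each view's local graph propagate the other views'
global similarities; the fused similarity is the mean of the final status
matrices, symmetrized. Weak, unsupported similarities fade while
similarities supported by several views are reinforced.

After each iteration every status matrix is renormalized back to the full-
kernel form (off-diagonal total 1/2, diagonal 1/2); the bare update drifts
numerically without it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import euclidean_distances

from .containers import CellSimilarity, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FusionConfig",
    "KernelPair",
    "affinity_kernel",
    "build_kernels",
    "snf_fuse",
    "scnpf_fusion",
    "SimilarityFusion",
]

_ALPHA_FLOOR = 1e-12


@dataclass
class FusionConfig:
    """Fusion hyperparameters: K nearest neighbours, kernel bandwidth
    factor beta in (0, 1), and T cross-diffusion iterations."""

    K: int = 20
    beta: float = 0.5
    T: int = 10

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if self.T < 0:
            raise ValueError("T must be nonnegative")


@dataclass
class KernelPair:
    """Full kernel P (rows sum to 1, diagonal 1/2) and sparse local kernel
    S (rows sum to 1 over each cell's neighbourhood). P may be asymmetric;
    symmetry is only enforced on the final fused output."""

    P: np.ndarray
    S: np.ndarray


def _check_K(K: int, n_cells: int) -> None:
    if K >= n_cells:
        raise ValueError(f"K={K} must be smaller than the number of cells ({n_cells})")


def _neighbour_order(row: np.ndarray, self_idx: int, cell_ids: list[str]) -> np.ndarray:
    """Indices of all other cells by decreasing affinity, ties broken by
    lexicographic cell id for determinism."""
    others = np.array([j for j in range(len(row)) if j != self_idx])
    keys = sorted(others, key=lambda j: (-row[j], cell_ids[j]))
    return np.array(keys)


def affinity_kernel(
    expr: ExpressionMatrix, cfg: FusionConfig | None = None
) -> CellSimilarity:
    """Scaled exponential affinity between cells of one expression matrix.

    Euclidean distances between per-cell profiles, locally scaled by the
    mean distance to each cell's K nearest neighbours. The diagonal takes
    the self-case value (d=0, so affinity 1).
    """
    cfg = cfg or FusionConfig()
    n = expr.n_cells
    if n < cfg.K + 2:
        raise ValueError(f"need at least K+2={cfg.K + 2} cells, got {n}")
    X = expr.values.T  # cells x genes
    D = euclidean_distances(X)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    # mean distance to the K nearest other cells
    D_sorted = np.sort(D, axis=1)
    mu = D_sorted[:, 1 : cfg.K + 1].mean(axis=1)
    alpha = (mu[:, None] + mu[None, :] + D) / 3.0
    if np.any(alpha <= 0):
        logger.warning(
            "kernel scale alpha hit zero (duplicate-heavy data); flooring at %g",
            _ALPHA_FLOOR,
        )
        alpha = np.maximum(alpha, _ALPHA_FLOOR)
    W = np.exp(-(D**2) / (cfg.beta * alpha))
    return CellSimilarity(list(expr.cell_ids), W)


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Row-normalize an affinity into the full kernel: off-diagonal entries
    sum to 1/2 per row, diagonal exactly 1/2."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsums = off.sum(axis=1)
    P = np.zeros_like(W)
    zero_rows = rowsums == 0
    if zero_rows.any():
        logger.warning(
            "%d cells have all-zero off-diagonal affinity; their full-kernel "
            "rows become point masses on the diagonal",
            int(zero_rows.sum()),
        )
    safe = np.where(zero_rows, 1.0, rowsums)
    P = off / (2.0 * safe[:, None])
    diag = np.where(zero_rows, 1.0, 0.5)
    P[np.arange(n), np.arange(n)] = diag
    return P


def build_kernels(sim: CellSimilarity, cfg: FusionConfig | None = None) -> KernelPair:
    """Derive the full kernel P and sparse K-nearest-neighbour kernel S
    from an affinity matrix.

    Each cell's neighbourhood is itself plus its K most similar other
    cells (|N_i| = K+1); affinity ties are broken by lexicographic cell id.
    """
    cfg = cfg or FusionConfig()
    W = sim.matrix
    n = sim.n_cells
    _check_K(cfg.K, n)
    P = _full_kernel(W)
    S = np.zeros_like(W)
    for i in range(n):
        nbr = _neighbour_order(W[i], i, sim.cell_ids)[: cfg.K]
        members = np.append(nbr, i)
        total = W[i, members].sum()
        if total == 0:
            S[i, i] = 1.0
            continue
        S[i, members] = W[i, members] / total
    return KernelPair(P=P, S=S)


def _align_views(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    ref = matrices[0]
    ref_set = set(ref.cell_ids)
    aligned = [ref]
    for m in matrices[1:]:
        diff = ref_set.symmetric_difference(m.cell_ids)
        if diff:
            raise ValueError(
                f"views disagree on cell ids; {len(diff)} differ, "
                f"e.g. {sorted(diff)[:5]}"
            )
        aligned.append(m.reorder_cells(list(ref.cell_ids)))
    return aligned


def snf_fuse(
    matrices: list[ExpressionMatrix], cfg: FusionConfig | None = None
) -> CellSimilarity:
    """Fuse two or more expression views into one cell similarity matrix.

    Views must share the same cell id set (aligned by id, not position);
    gene sets may differ freely. With T=0 the result is the mean of the
    initial full kernels.
    """
    cfg = cfg or FusionConfig()
    if len(matrices) < 2:
        raise ValueError("fusion requires >= 2 views")
    matrices = _align_views(matrices)
    cell_ids = list(matrices[0].cell_ids)
    kernels = [build_kernels(affinity_kernel(m, cfg), cfg) for m in matrices]
    Ps = [kp.P for kp in kernels]
    Ss = [kp.S for kp in kernels]
    m = len(Ps)
    for _ in range(cfg.T):
        new = []
        for a in range(m):
            others = np.mean([Ps[b] for b in range(m) if b != a], axis=0)
            updated = Ss[a] @ others @ Ss[a].T
            new.append(_full_kernel(updated))
        Ps = new
    Po = np.mean(Ps, axis=0)
    Po = (Po + Po.T) / 2.0
    return CellSimilarity(cell_ids, Po)


def scnpf_fusion(
    expr_list: list[ExpressionMatrix], cfg: FusionConfig | None = None
) -> CellSimilarity:
    """Fuse raw and/or propagated expression matrices (any combination of
    views over the same cells) into one similarity matrix."""
    return snf_fuse(list(expr_list), cfg)


class SimilarityFusion(BaseEstimator):
    """Similarity network fusion with a scikit-learn estimator interface.

    Parameters
    ----------
    K : int
        Number of nearest neighbours in the sparse kernel (default 20).
    beta : float
        Kernel bandwidth hyperparameter in (0, 1) (default 0.5).
    T : int
        Cross-diffusion iterations (default 10).

    Attributes
    ----------
    fused_similarity_ : CellSimilarity
        The fused cell-cell similarity after :meth:`fit`.
    """

    def __init__(self, K: int = 20, beta: float = 0.5, T: int = 10):
        self.K = K
        self.beta = beta
        self.T = T

    def _config(self) -> FusionConfig:
        return FusionConfig(K=self.K, beta=self.beta, T=self.T)

    def fit(self, X: list[ExpressionMatrix], y=None) -> "SimilarityFusion":
        """Fuse a list of expression views sharing the same cells."""
        self.fused_similarity_ = snf_fuse(list(X), self._config())
        return self

    def fit_transform(self, X: list[ExpressionMatrix], y=None) -> CellSimilarity:
        return self.fit(X).fused_similarity_
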
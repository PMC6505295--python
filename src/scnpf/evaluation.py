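"""Clustering front-ends and evaluation metrics for cell similarity matrices.

Four clustering algorithms operate on a similarity matrix: k-means on its
rows as feature vectors, spectral clustering via the normalized-Laplacian
embedding of the affinity, average-linkage hierarchical clustering and PAM
(partitioning around medoids), both on the dissimilarity max(sim) - sim.

External metrics against known labels: adjusted Rand index, pair-counting
Jaccard, purity, and normalized mutual information. Internal metrics on
the clustered representation: Davies-Bouldin index, Dunn index, and the
connectivity penalty (reciprocal ranks of nearest neighbours placed in a
different cluster). Smaller connectivity/DBI or larger Dunn indicate
better separation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy
import scipy.spatial.distance
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans, spectral_clustering
from sklearn.metrics import (
    adjusted_rand_score,
    euclidean_distances,
    normalized_mutual_info_score,
)

from .containers import CellSimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "cluster_similarity",
    "external_metrics",
    "internal_metrics",
    "evaluate_similarity",
    "SimilarityClusterer",
]

_METHODS = ("kmeans", "spectral", "hierarchical", "pam")
_NMI_AVERAGE = {"sqrt": "geometric", "min": "min", "max": "max"}


@dataclass
class ClusteringResult:
    """Per-cell integer labels plus the settings that produced them."""

    labels: np.ndarray
    method: str
    k: int
    seed: int


def _dissimilarity(sim: np.ndarray) -> np.ndarray:
    d = sim.max() - sim
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _pam(dissim: np.ndarray, k: int) -> np.ndarray:
    """Classic PAM: greedy BUILD then SWAP until no improving swap.

    Deterministic; ties resolve to the lowest index.
    """
    n = dissim.shape[0]
    medoids = [int(np.argmin(dissim.sum(axis=1)))]
    while len(medoids) < k:
        current = dissim[:, medoids].min(axis=1)
        gains = np.maximum(current[:, None] - dissim, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(dissim[:, meds].min(axis=1).sum())

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1 :])
                c = cost(trial)
                if c < best - 1e-12:
                    best, medoids, improved = c, trial, True
        # restart the scan after any accepted swap
    return np.argmin(dissim[:, medoids], axis=1)


def cluster_similarity(
    sim: CellSimilarity, k: int, method: str = "spectral", seed: int = 1000
) -> ClusteringResult:
    """Cluster cells from a similarity matrix.

    k-means treats the similarity rows as feature vectors; spectral
    clustering uses the similarity directly as the affinity; hierarchical
    (average linkage) and PAM run on the dissimilarity max(sim) - sim.
    Deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= sim.n_cells:
        raise ValueError(f"k={k} must be smaller than the number of cells ({sim.n_cells})")
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    M = sim.matrix
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, max_iter=10_000, random_state=seed)
        labels = km.fit_predict(M)
    elif method == "spectral":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # graph-connectivity chatter
            labels = spectral_clustering(
                M, n_clusters=k, random_state=seed, assign_labels="kmeans"
            )
    elif method == "hierarchical":
        condensed = scipy.spatial.distance.squareform(_dissimilarity(M), checks=False)
        Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
        labels = scipy.cluster.hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    else:  # pam
        labels = _pam(_dissimilarity(M), k)
    return ClusteringResult(labels=np.asarray(labels, dtype=int), method=method, k=k, seed=seed)


def _contingency(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(table, (pi, ti), 1)
    return table


def external_metrics(pred, truth, nmi_average: str = "sqrt") -> dict[str, float]:
    """Agreement between a predicted and a reference partition.

    Returns ``{"ari", "jaccard", "purity", "nmi"}``. Jaccard counts pairs
    co-clustered in both partitions over pairs co-clustered in either.
    NMI uses the geometric-mean normalization by default (``"min"`` and
    ``"max"`` are also available). When both partitions are a single
    identical class all metrics are 1 by convention.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1-D label vectors")
    if pred.size < 2:
        raise ValueError("need at least 2 observations")
    table = _contingency(pred, truth)
    n = pred.size

    def pairs(x):
        return (x * (x - 1) // 2).sum()

    n11 = pairs(table)
    pred_pairs = pairs(table.sum(axis=1))
    truth_pairs = pairs(table.sum(axis=0))
    union = pred_pairs + truth_pairs - n11
    jaccard = 1.0 if union == 0 else float(n11 / union)
    purity = float(table.max(axis=1).sum() / n)

    if table.shape == (1, 1):
        logger.warning(
            "both partitions are a single class; metrics are 1 by convention"
        )
        return {"ari": 1.0, "jaccard": 1.0, "purity": 1.0, "nmi": 1.0}
    ari = float(adjusted_rand_score(truth, pred))
    nmi = float(
        normalized_mutual_info_score(
            truth, pred, average_method=_NMI_AVERAGE[nmi_average]
        )
    )
    return {"ari": ari, "jaccard": jaccard, "purity": purity, "nmi": nmi}


def _davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index with Euclidean centroids.

    Mean over clusters of the worst (s_i + s_j) / d(c_i, c_j) ratio, where
    s is the average member-to-centroid distance. Zero-scatter clusters
    (singletons) contribute zero ratios, so two singleton clusters score 0.
    """
    uniq = np.unique(labels)
    centroids = np.array([points[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array(
        [
            np.linalg.norm(points[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(uniq)
        ]
    )
    k = uniq.size
    worst = np.zeros(k)
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            s = scatter[i] + scatter[j]
            ratios.append(0.0 if s == 0 else (s / d if d > 0 else np.inf))
        worst[i] = max(ratios)
    return float(worst.mean())


def internal_metrics(
    points: np.ndarray, labels, neighbor_size: int = 10
) -> dict[str, float]:
    """Label-free cluster-separation scores on a point representation.

    ``points`` holds one observation per row (for similarity-based
    clustering, pass the representation the clusterer used, e.g. the
    similarity rows). Returns ``{"connectivity", "dbi", "dunn"}``.
    Dunn is +inf when every cluster is a singleton (no within-cluster
    diameter).
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or points.shape[0] != labels.size:
        raise ValueError("points must be 2-D with one row per labelled observation")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("internal metrics need at least 2 clusters")
    n = points.shape[0]
    D = euclidean_distances(points)

    # connectivity: reciprocal ranks of nearest neighbours in other clusters
    L = min(neighbor_size, n - 1)
    D_self = D.copy()
    np.fill_diagonal(D_self, np.inf)
    order = np.argsort(D_self, axis=1, kind="stable")
    conn = 0.0
    for i in range(n):
        for j in range(L):
            if labels[order[i, j]] != labels[i]:
                conn += 1.0 / (j + 1)

    same = labels[:, None] == labels[None, :]
    off = ~np.eye(n, dtype=bool)
    max_diam = D[same & off].max() if (same & off).any() else 0.0
    min_sep = D[~same].min()
    if max_diam == 0.0:
        logger.warning("all clusters are singletons; Dunn reported as +inf")
        dunn = np.inf
    else:
        dunn = float(min_sep / max_diam)

    dbi = _davies_bouldin(points, labels)
    return {"connectivity": float(conn), "dbi": dbi, "dunn": dunn}


def evaluate_similarity(
    sim: CellSimilarity,
    k: int,
    truth=None,
    method: str = "kmeans",
    n_runs: int = 10,
    seed: int = 1000,
    neighbor_size: int = 10,
) -> dict:
    """Cluster a similarity matrix ``n_runs`` times (seeds seed..seed+n-1)
    and bundle per-run metrics with their medians.

    Internal metrics use the similarity rows as the point representation
    (the same representation k-means clusters). External metrics are
    included when ``truth`` labels are given.
    """
    runs = []
    for i in range(n_runs):
        res = cluster_similarity(sim, k, method=method, seed=seed + i)
        entry: dict = {"seed": res.seed, "labels": res.labels.tolist()}
        entry.update(internal_metrics(sim.matrix, res.labels, neighbor_size))
        if truth is not None:
            entry.update(external_metrics(res.labels, truth))
        runs.append(entry)
    keys = [k_ for k_ in runs[0] if k_ not in ("seed", "labels")]
    medians = {k_: float(np.median([r[k_] for r in runs])) for k_ in keys}
    return {"method": method, "k": k, "runs": runs, "median": medians}


class SimilarityClusterer(BaseEstimator, ClusterMixin):
    """Similarity-matrix clustering with a scikit-learn estimator interface.

    Parameters
    ----------
    n_clusters : int
        Number of clusters (the number of cell types).
    method : {"kmeans", "spectral", "hierarchical", "pam"}
    seed : int
        Random seed for the stochastic methods (default 1000).

    Attributes
    ----------
    labels_ : ndarray of int
        Per-cell cluster assignment after :meth:`fit`.
    """

    def __init__(self, n_clusters: int = 2, method: str = "spectral", seed: int = 1000):
        self.n_clusters = n_clusters
        self.method = method
        self.seed = seed

    def fit(self, X: CellSimilarity, y=None) -> "SimilarityClusterer":
        result = cluster_similarity(X, self.n_clusters, self.method, self.seed)
        self.labels_ = result.labels
        return self

    def fit_predict(self, X: CellSimilarity, y=None) -> np.ndarray:
        return self.fit(X).labels_
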
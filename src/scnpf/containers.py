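"""Core in-memory containers shared by all modules.

The canonical orientation everywhere in this package is genes-as-rows,
cells-as-columns, matching the gene-cell expression matrix convention of
single-cell preprocessing tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionMatrix", "GeneNetwork", "CellSimilarity", "TransitionMatrix"]


def _as_id_list(ids, what: str) -> list[str]:
    out = [str(i) for i in ids]
    if len(set(out)) != len(out):
        seen, dup = set(), []
        for i in out:
            if i in seen:
                dup.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} ids: {dup[:5]}")
    return out


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of nonnegative expression values.

    Parameters
    ----------
    values
        Dense 2-D array, shape ``(n_genes, n_cells)``. Counts or smoothed
        abundances; must be finite and nonnegative.
    gene_ids, cell_ids
        Ordered, duplicate-free identifiers for rows and columns.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = _as_id_list(self.gene_ids, "gene")
        self.cell_ids = _as_id_list(self.cell_ids, "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain NaN or Inf")
        if np.any(self.values < 0):
            raise ValueError("expression values contain negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def zero_fraction(self) -> float:
        return float(np.mean(self.values == 0))

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Restrict to genes selected by a boolean mask, preserving order."""
        mask = np.asarray(mask, dtype=bool)
        ids = [g for g, m in zip(self.gene_ids, mask) if m]
        return ExpressionMatrix(self.values[mask, :], ids, list(self.cell_ids))

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Restrict to cells selected by a boolean mask, preserving order."""
        mask = np.asarray(mask, dtype=bool)
        ids = [c for c, m in zip(self.cell_ids, mask) if m]
        return ExpressionMatrix(self.values[:, mask], list(self.gene_ids), ids)

    def reorder_cells(self, cell_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy with columns rearranged into the given cell order."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValueError(f"unknown cell ids: {missing[:5]}")
        idx = [pos[c] for c in cell_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(cell_ids))


@dataclass
class GeneNetwork:
    """A weighted undirected gene-gene graph as a symmetric adjacency matrix.

    The adjacency carries nonnegative edge weights, has a zero diagonal
    (no self-loops) and is exactly symmetrized on construction after a
    1e-12 symmetry check.
    """

    node_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = _as_id_list(self.node_ids, "node")
        a = np.asarray(self.adjacency, dtype=float)
        n = len(self.node_ids)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} does not match {n} nodes")
        if not np.all(np.isfinite(a)):
            raise ValueError("adjacency contains NaN or Inf")
        if np.any(a < 0):
            raise ValueError("adjacency contains negative weights")
        if n and np.max(np.abs(a - a.T)) > 1e-12:
            raise ValueError("adjacency is not symmetric (tolerance 1e-12)")
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 0.0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def degrees(self) -> np.ndarray:
        """Weighted degree (column sums; equal to row sums by symmetry)."""
        return self.adjacency.sum(axis=0)

    def subnetwork(self, node_ids: list[str]) -> "GeneNetwork":
        pos = {g: i for i, g in enumerate(self.node_ids)}
        idx = [pos[g] for g in node_ids]
        return GeneNetwork(list(node_ids), self.adjacency[np.ix_(idx, idx)])


@dataclass
class CellSimilarity:
    """A symmetric nonnegative cells x cells similarity matrix."""

    cell_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _as_id_list(self.cell_ids, "cell")
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.cell_ids)
        if n == 0:
            raise ValueError("similarity over zero cells is not meaningful")
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} cells")
        if not np.all(np.isfinite(m)):
            raise ValueError("similarity contains NaN or Inf")
        if np.any(m < 0):
            raise ValueError("similarity contains negative entries")
        if np.max(np.abs(m - m.T)) > 1e-8:
            raise ValueError("similarity is not symmetric (tolerance 1e-8)")
        self.matrix = (m + m.T) / 2.0

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class TransitionMatrix:
    """Column-normalized adjacency ``W = B D^-1`` driving the random walk.

    Every column sums to one except columns of isolated nodes, which are
    all-zero.
    """

    node_ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = _as_id_list(self.node_ids, "node")
        w = np.asarray(self.W, dtype=float)
        n = len(self.node_ids)
        if w.shape != (n, n):
            raise ValueError(f"W shape {w.shape} does not match {n} nodes")
        if np.any(w < 0):
            raise ValueError("transition matrix contains negative entries")
        colsums = w.sum(axis=0)
        bad = ~(np.isclose(colsums, 1.0, atol=1e-10) | (colsums == 0.0))
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} columns are neither stochastic nor all-zero"
            )
        self.W = w

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def isolated(self) -> np.ndarray:
        """Boolean mask of nodes whose column is all-zero."""
        return self.W.sum(axis=0) == 0.0
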
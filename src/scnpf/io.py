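"""Readers and writers for expression matrices, gene networks, similarity
matrices and label vectors.

Formats are plain text: dense CSV/TSV with a header row of cell ids and a
first column of gene ids, MatrixMarket coordinate files with ``.genes.txt`` /
``.cells.txt`` sidecars, 3-column edge lists, and 2-column label tables.
Row/column order is always preserved exactly as found in the file; readers
never silently transpose (orientation is a declared argument).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CellSimilarity, ExpressionMatrix, GeneNetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_similarity",
    "write_similarity",
    "read_labels",
    "write_labels",
]

_DELIMS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("mtx", "csv", "tsv"):
        return suffix
    raise ValueError(f"cannot infer format from suffix of {path}; pass format=")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.txt"), stem.with_suffix(".cells.txt")


def read_expression(
    path, format: str | None = None, genes_as_rows: bool = True
) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    Parameters
    ----------
    path
        CSV/TSV with gene ids in the first column and cell ids in the
        header, or a MatrixMarket ``.mtx`` file with ``<stem>.genes.txt``
        and ``<stem>.cells.txt`` sidecars (one id per line).
    format
        ``"mtx"``, ``"csv"`` or ``"tsv"``; inferred from the suffix if
        omitted.
    genes_as_rows
        Declared orientation of the file. When False the file stores cells
        as rows and is transposed on load. The reader never guesses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        gpath, cpath = _sidecar_paths(path)
        for p in (gpath, cpath):
            if not p.exists():
                raise ValueError(f"missing MTX sidecar file {p}")
        values = scipy.sparse.coo_matrix(scipy.io.mmread(path)).toarray()
        gene_ids = gpath.read_text().split()
        cell_ids = cpath.read_text().split()
    elif fmt in _DELIMS:
        df = pd.read_csv(path, sep=_DELIMS[fmt], index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    if not genes_as_rows:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    return ExpressionMatrix(values, gene_ids, cell_ids)


def write_expression(expr: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write an expression matrix as CSV/TSV or MTX (+ id sidecars)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        gpath, cpath = _sidecar_paths(path)
        scipy.io.mmwrite(os.fspath(path), scipy.sparse.coo_matrix(expr.values))
        gpath.write_text("\n".join(expr.gene_ids) + "\n")
        cpath.write_text("\n".join(expr.cell_ids) + "\n")
    elif fmt in _DELIMS:
        df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids)
        df.to_csv(path, sep=_DELIMS[fmt])
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


def read_network(path) -> GeneNetwork:
    """Read a weighted undirected gene network from a 3-column edge list.

    Columns are gene_a, gene_b, weight (whitespace or tab separated,
    ``#`` comments allowed). Duplicate edges keep the maximum weight;
    self-loops are dropped; weights must be nonnegative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(
            f"edge list {path} must have 3 columns (gene_a gene_b weight), "
            f"found {df.shape[1]}"
        )
    a = df.iloc[:, 0].astype(str).to_numpy()
    b = df.iloc[:, 1].astype(str).to_numpy()
    w = df.iloc[:, 2].astype(float).to_numpy()
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError(f"edge list {path} contains negative or non-finite weights")
    return network_from_edges(list(zip(a, b, w)))


def network_from_edges(edges) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from (gene_a, gene_b, weight) triples.

    Node order follows first appearance in the edge list; duplicate edges
    resolve to the maximum weight (order-independent); self-loops dropped.
    """
    nodes: dict[str, int] = {}
    for a, b, _ in edges:
        for g in (str(a), str(b)):
            if g not in nodes:
                nodes[g] = len(nodes)
    n = len(nodes)
    adj = np.zeros((n, n))
    for a, b, w in edges:
        i, j = nodes[str(a)], nodes[str(b)]
        if i == j:
            continue
        w = float(w)
        if w < 0:
            raise ValueError(f"negative edge weight {w} on ({a}, {b})")
        if w > adj[i, j]:
            adj[i, j] = adj[j, i] = w
    return GeneNetwork(list(nodes), adj)


def write_network(net: GeneNetwork, path, min_weight: float = 0.0) -> None:
    """Write the upper triangle of a network as a 3-column TSV edge list.

    Edges with weight <= ``min_weight`` are omitted, bounding file size for
    dense co-expression networks.
    """
    path = Path(path)
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    with open(path, "w") as fh:
        for i, j in zip(iu, ju):
            w = net.adjacency[i, j]
            if w > min_weight:
                fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\t{w:.12g}\n")


def read_similarity(path) -> CellSimilarity:
    """Read a cell-cell similarity matrix from TSV (ids in header and
    first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError(f"row/column cell ids disagree in {path}")
    return CellSimilarity(ids, df.to_numpy(dtype=float))


def write_similarity(sim: CellSimilarity, path) -> None:
    """Write a cell-cell similarity matrix as TSV with ids on both axes."""
    df = pd.DataFrame(sim.matrix, index=sim.cell_ids, columns=sim.cell_ids)
    df.to_csv(path, sep="\t", float_format="%.15g")


def read_labels(path) -> tuple[list[str], np.ndarray]:
    """Read a 2-column (cell_id, label) TSV; returns (cell_ids, labels)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} must have 2 columns")
    ids = [str(c) for c in df.iloc[:, 0]]
    labels = df.iloc[:, 1].to_numpy()
    return ids, labels


def write_labels(cell_ids, labels, path) -> None:
    with open(path, "w") as fh:
        for c, l in zip(cell_ids, labels):
            fh.write(f"{c}\t{l}\n")
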
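"""Graph readers and writers: 3-column edge-list TSV and MatrixMarket.

Edge-list TSV columns are (node_i, node_j, weight) with 0-based node ids;
undirected graphs are stored as the upper triangle.  MatrixMarket uses the
standard 1-based coordinate format (shifted on I/O).  Round trips are
lossless for rational weights (weights written with repr precision).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .graphs import WeightedGraph

__all__ = ["load_graph", "save_graph"]

_DIRECTED_HEADER = "# directed"


def save_graph(graph: WeightedGraph, path: str | Path) -> None:
    """Write a graph as edge-list TSV (``.tsv``) or MatrixMarket (``.mtx``)."""
    path = Path(path)
    if path.suffix == ".mtx":
        W = scipy.sparse.coo_matrix(graph.weights)
        scipy.io.mmwrite(
            path,
            W,
            comment="directed" if graph.directed else "",
            precision=17,
            symmetry="general",
        )
        return
    lines = []
    if graph.directed:
        lines.append(_DIRECTED_HEADER)
    W = graph.weights
    n = graph.n_nodes
    lines.append(f"# nodes\t{n}")
    ii, jj = np.nonzero(W)
    for i, j in zip(ii, jj):
        if not graph.directed and j < i:
            continue
        lines.append(f"{i}\t{j}\t{float(W[i, j])!r}")
    path.write_text("\n".join(lines) + "\n")


def load_graph(path: str | Path, *, directed: bool | None = None) -> WeightedGraph:
    """Read an edge-list TSV or MatrixMarket graph file.

    Undirected inputs must be symmetric (or stored as one triangle, which is
    symmetrized); an asymmetric matrix is rejected unless flagged directed
    — either by the ``directed`` argument or by a ``# directed`` comment
    (TSV) / ``%directed`` comment (MatrixMarket) in the file.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        text = path.read_text()
        file_directed = any(
            line.startswith("%") and "directed" in line.lower()
            for line in text.splitlines()[:5]
        )
        M = scipy.io.mmread(io.StringIO(text))
        if scipy.sparse.issparse(M):
            M = M.toarray()
        W = np.asarray(M, dtype=float)
        return _finalize(W, directed, file_directed, path)
    n_decl = None
    entries: list[tuple[int, int, float]] = []
    file_directed = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line == _DIRECTED_HEADER:
                file_directed = True
            elif line.startswith("# nodes"):
                n_decl = int(line.split("\t")[1])
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        try:
            i, j, w = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: malformed edge line ({err})") from err
        if i < 0 or j < 0:
            raise ValueError(f"{path}:{lineno}: node ids must be nonnegative (0-based)")
        entries.append((i, j, w))
    if not entries:
        raise ValueError(f"{path}: no edges found")
    n = n_decl if n_decl is not None else max(max(i, j) for i, j, _ in entries) + 1
    W = np.zeros((n, n))
    for i, j, w in entries:
        W[i, j] = w
        if not file_directed and not (directed or False):
            W[j, i] = w
    return _finalize(W, directed, file_directed, path)


def _finalize(
    W: np.ndarray, directed: bool | None, file_directed: bool, path: Path
) -> WeightedGraph:
    is_directed = file_directed if directed is None else directed
    if not is_directed and not np.allclose(W, W.T, atol=1e-12, rtol=0):
        raise ValueError(
            f"{path}: asymmetric weights in an input not flagged directed "
            "(only the separable model may be directed)"
        )
    if np.any(W < 0):
        raise ValueError(f"{path}: negative weights are not allowed")
    return WeightedGraph(W, directed=is_directed)
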
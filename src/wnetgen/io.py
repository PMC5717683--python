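"""Reading and writing networks, trajectories and convergence maps.

Three dialects are supported, all plain text:

* ``matrix`` — square CSV/TSV (n rows x n columns, optional header row of
  1-based node IDs; delimiter comma for ``.csv``, tab otherwise);
* ``edgelist`` — TSV with columns ``node_i  node_j  weight`` (1-based IDs,
  each symmetric edge listed once, a ``# n=<count>`` comment carrying the
  node count);
* ``graphml`` — weighted undirected graph with the weight stored in the edge
  attribute ``weight``.

Zero off-diagonals (matrix dialect) and absent pairs (edge list, GraphML)
become structural zeros — pairs marked disconnected in the network's
pattern.  Writers are deterministic (ascending node IDs, lexicographic
edges, shortest exact float representation), so writing the same network
twice produces byte-identical files and a write/read round trip reproduces
weights bit-exactly.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ParseError
from .feasibility import ConvergenceMap
from .generator import GenerationResult
from .network import StructurePattern, WeightedNetwork

__all__ = [
    "read_network",
    "write_network",
    "write_trajectory",
    "write_map",
]

_DIALECTS = ("matrix", "edgelist", "graphml")


def _guess_dialect(path: Path) -> str:
    ext = path.suffix.lower()
    if ext == ".graphml":
        return "graphml"
    if ext in (".edges", ".edgelist", ".el"):
        return "edgelist"
    return "matrix"


def _fmt(x: float) -> str:
    # repr of a Python float is the shortest string that round-trips exactly
    return repr(float(x))


def _net_from_dense(mat: np.ndarray, symmetric: bool = True) -> WeightedNetwork:
    n = mat.shape[0]
    disconnected = frozenset(
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if mat[i, j] == 0.0 and mat[j, i] == 0.0
    )
    return WeightedNetwork(mat, StructurePattern(n, disconnected, symmetric))


def read_network(path: str | Path, dialect: str = "auto") -> WeightedNetwork:
    """Read a network file; ``dialect`` in {auto, matrix, edgelist, graphml}."""
    path = Path(path)
    if dialect == "auto":
        dialect = _guess_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "graphml":
        return _read_graphml(path)
    if dialect == "edgelist":
        return _read_edgelist(path)
    return _read_matrix(path)


def write_network(net: WeightedNetwork, path: str | Path, dialect: str = "auto") -> None:
    """Write a network deterministically in the requested dialect."""
    path = Path(path)
    if dialect == "auto":
        dialect = _guess_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "graphml":
        _write_graphml(net, path)
    elif dialect == "edgelist":
        _write_edgelist(net, path)
    else:
        _write_matrix(net, path)


# -- matrix dialect ---------------------------------------------------------

def _read_matrix(path: Path) -> WeightedNetwork:
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    raw: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        raw.append((lineno, [f.strip() for f in line.split(delim)]))
    if not raw:
        raise ParseError(f"{path}: no matrix rows found")

    def is_header(fields: list[str]) -> bool:
        try:
            values = [float(f) for f in fields if f]
        except ValueError:
            return True  # non-numeric labels
        # a numeric row of consecutive node IDs 1..k atop k data rows
        return values == list(range(1, len(values) + 1)) and len(raw) == len(values) + 1

    if is_header(raw[0][1]):
        raw = raw[1:]
    rows: list[list[float]] = []
    for lineno, fields in raw:
        try:
            rows.append([float(f) for f in fields if f != ""])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric entry ({exc})") from None
    widths = {len(r) for r in rows}
    if len(widths) != 1 or widths.pop() != len(rows):
        raise ParseError(
            f"{path}: matrix is not square ({len(rows)} rows, widths {sorted({len(r) for r in rows})})"
        )
    mat = np.array(rows)
    _check_entries(mat, path)
    return _net_from_dense(mat, symmetric=bool(np.array_equal(mat, mat.T)))


def _write_matrix(net: WeightedNetwork, path: Path) -> None:
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    lines = [delim.join(str(k + 1) for k in range(net.n))]
    for i in range(net.n):
        lines.append(delim.join(_fmt(net.weights[i, j]) for j in range(net.n)))
    path.write_text("\n".join(lines) + "\n")


# -- edge-list dialect ------------------------------------------------------

def _read_edgelist(path: Path) -> WeightedNetwork:
    n = 0
    edges: list[tuple[int, int, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if stripped.replace(" ", "").startswith("#n="):
                n = int(stripped.split("=", 1)[1])
            continue
        fields = stripped.split()
        if fields[:3] == ["node_i", "node_j", "weight"]:
            continue
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 'node_i node_j weight', got {line!r}")
        try:
            i, j, w = int(fields[0]), int(fields[1]), float(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if i < 1 or j < 1:
            raise ParseError(f"{path}:{lineno}: node IDs are 1-based, got ({i}, {j})")
        if i == j:
            raise ParseError(f"{path}:{lineno}: self-loop on node {i} (diagonal must be zero)")
        if w < 0:
            raise ParseError(f"{path}:{lineno}: negative weight {w}")
        edges.append((i - 1, j - 1, w))
    n_seen = max((max(i, j) + 1 for i, j, _ in edges), default=0)
    if n and n_seen > n:
        raise ParseError(f"{path}: node ID {n_seen} exceeds declared node count {n}")
    n = max(n, n_seen)
    if n < 2:
        raise ParseError(f"{path}: fewer than 2 nodes")
    mat = np.zeros((n, n))
    for i, j, w in edges:
        mat[i, j] = mat[j, i] = w
    return _net_from_dense(mat)


def _write_edgelist(net: WeightedNetwork, path: Path) -> None:
    lines = [f"# n={net.n}", "node_i\tnode_j\tweight"]
    for i in range(net.n):
        for j in range(i + 1, net.n):
            w = net.weights[i, j]
            if w != 0.0:
                lines.append(f"{i + 1}\t{j + 1}\t{_fmt(w)}")
    path.write_text("\n".join(lines) + "\n")


# -- GraphML dialect --------------------------------------------------------

def _read_graphml(path: Path) -> WeightedNetwork:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:
        raise ParseError(f"{path}: not valid GraphML ({exc})") from None
    try:
        nodes = sorted(g.nodes, key=int)
    except ValueError:
        raise ParseError(f"{path}: node IDs must be integers (1-based)") from None
    n = len(nodes)
    index = {node: k for k, node in enumerate(nodes)}
    mat = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 0.0))
        if w < 0:
            raise ParseError(f"{path}: negative weight on edge ({u}, {v})")
        if u == v:
            raise ParseError(f"{path}: self-loop on node {u}")
        mat[index[u], index[v]] = mat[index[v], index[u]] = w
    return _net_from_dense(mat)


def _write_graphml(net: WeightedNetwork, path: Path) -> None:
    g = nx.Graph()
    for k in range(net.n):
        g.add_node(str(k + 1))
    for i in range(net.n):
        for j in range(i + 1, net.n):
            w = net.weights[i, j]
            if w != 0.0:
                g.add_edge(str(i + 1), str(j + 1), weight=float(w))
    nx.write_graphml(g, path)


# -- tidy exports -----------------------------------------------------------

def write_trajectory(result: GenerationResult, path: str | Path) -> None:
    """Objective trajectory as tidy TSV (iteration, objective, dr, dv, ds)."""
    lines = ["iteration\tobjective\tdr\tdv\tds"]
    for p in result.trajectory:
        lines.append(
            f"{p.iteration}\t{_fmt(p.objective)}\t{_fmt(p.dr)}\t{_fmt(p.dv)}\t{_fmt(p.ds)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_map(cmap: ConvergenceMap, path: str | Path) -> None:
    """Convergence map as TSV (v_star, s_star, converged, achieved metrics)."""
    lines = ["v_star\ts_star\tconverged\tr_achieved\tv_achieved\ts_achieved"]
    for rec in cmap.grid:
        def cell(x: float | None) -> str:
            return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else _fmt(x)

        lines.append(
            f"{_fmt(rec.v_star)}\t{_fmt(rec.s_star)}\t{int(rec.converged)}\t"
            f"{cell(rec.r_achieved)}\t{cell(rec.v_achieved)}\t{cell(rec.s_achieved)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- helpers ----------------------------------------------------------------

def _check_entries(mat: np.ndarray, path: Path) -> None:
    n = mat.shape[0]
    for i in range(n):
        if mat[i, i] != 0.0:
            raise ParseError(f"{path}: nonzero diagonal entry at node {i + 1}")
    if np.any(mat < 0):
        i, j = np.argwhere(mat < 0)[0]
        raise ParseError(f"{path}: negative weight at ({i + 1}, {j + 1})")
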
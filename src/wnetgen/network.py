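"""Core domain types: structure patterns and weighted networks.

A weighted network is a square, zero-diagonal, nonnegative real matrix ``A``
whose entry ``a_ij`` is the weight (e.g. cost of movement, in km) of the edge
between nodes *i* and *j*.  A structure pattern records which node pairs are
forced to weight zero (disconnected) and whether the network is symmetric
(bidirectional edges of equal weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import InvalidNetworkError

__all__ = ["StructurePattern", "WeightedNetwork"]


def _canonical_pairs(pairs, n: int) -> frozenset[tuple[int, int]]:
    out = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"pair ({i}, {i}) is a self-loop; the diagonal is always zero")
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"pair ({i}, {j}) references a node outside 0..{n - 1}")
        out.add((min(i, j), max(i, j)))
    return frozenset(out)


@dataclass(frozen=True)
class StructurePattern:
    """Structural rules a network must obey.

    Parameters
    ----------
    n:
        Node count (>= 2).
    disconnected:
        Unordered node pairs (0-based) forced to weight zero.
    symmetric:
        Whether edge weights are required to be symmetric (``a_ij = a_ji``).
    """

    n: int
    disconnected: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need at least 2 nodes, got n={self.n}")
        object.__setattr__(
            self, "disconnected", _canonical_pairs(self.disconnected, self.n)
        )

    def connected_pairs(self) -> list[tuple[int, int]]:
        """Upper-triangle node pairs that may carry a nonzero weight."""
        return [
            (i, j)
            for i in range(self.n)
            for j in range(i + 1, self.n)
            if (i, j) not in self.disconnected
        ]

    def is_disconnected_pair(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.disconnected


@dataclass(frozen=True)
class WeightedNetwork:
    """A validated weighted adjacency matrix with its structure pattern.

    Invariants enforced at construction: square matrix, exactly zero diagonal,
    nonnegative finite off-diagonals, symmetry when the pattern requires it,
    and exact zeros on every disconnected pair.
    """

    weights: np.ndarray
    pattern: StructurePattern

    def __post_init__(self) -> None:
        w = np.array(self.weights, dtype=float, copy=True)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidNetworkError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] != self.pattern.n:
            raise InvalidNetworkError(
                f"matrix size {w.shape[0]} does not match pattern n={self.pattern.n}"
            )
        if not np.all(np.isfinite(w)):
            raise InvalidNetworkError("weight matrix contains NaN or infinite entries")
        if np.any(np.diagonal(w) != 0.0):
            raise InvalidNetworkError("diagonal entries must be exactly zero")
        if np.any(w < 0.0):
            raise InvalidNetworkError("edge weights must be nonnegative")
        if self.pattern.symmetric and not np.array_equal(w, w.T):
            raise InvalidNetworkError("pattern requires a symmetric matrix")
        for i, j in self.pattern.disconnected:
            if w[i, j] != 0.0 or w[j, i] != 0.0:
                raise InvalidNetworkError(
                    f"pair ({i}, {j}) is marked disconnected but carries weight"
                )
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_matrix(cls, weights, disconnected=(), symmetric: bool = True) -> "WeightedNetwork":
        """Build a network from a raw matrix, inferring the node count."""
        w = np.asarray(weights, dtype=float)
        n = w.shape[0] if w.ndim == 2 else 0
        return cls(w, StructurePattern(n, frozenset(disconnected), symmetric))

    @property
    def n(self) -> int:
        return self.pattern.n

    def is_connected(self) -> bool:
        """True when the nonzero pattern forms one connected component."""
        adj = csr_matrix((self.weights != 0).astype(np.int8))
        ncomp, _ = connected_components(adj, directed=False)
        return ncomp == 1

    def permuted(self, order) -> "WeightedNetwork":
        """Relabel nodes by ``order`` (node k of the result is node order[k])."""
        order = np.asarray(order, dtype=int)
        w = self.weights[np.ix_(order, order)]
        inv = np.empty_like(order)
        inv[order] = np.arange(self.n)
        disc = frozenset((int(inv[i]), int(inv[j])) for i, j in self.pattern.disconnected)
        return WeightedNetwork(w, StructurePattern(self.n, disc, self.pattern.symmetric))

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        """Same pattern, new weights (revalidated)."""
        return WeightedNetwork(weights, self.pattern)
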
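"""Linear equality constraints on the vectorized adjacency matrix.

The structural rules — zero diagonal, forced disconnections, symmetry — are
encoded as a linear system ``B @ vec(A) = E`` over the n^2 vectorized entries
of the matrix (row-major order: entry ``a_ij`` occupies slot ``i*n + j``).
``B`` is n^2 x n^2 with one row per constraint equation and the remaining
rows empty (all zero); ``E`` is the zero vector for every rule kind.

Row layout (one row per vectorized slot, so the system is reproducible):

* slot of ``a_ii``            -> diagonal row: coefficient 1 at ``a_ii``;
* slots of a disconnected pair -> two disconnection rows, coefficient 1 at
  ``a_ij`` and at ``a_ji`` respectively;
* upper slot of a connected pair (symmetric patterns) -> symmetry row,
  coefficients +1 at ``a_ij`` and -1 at ``a_ji``; the lower slot's row stays
  empty.

The optimizer never solves this system: it works in a reduced *free
parameterization* (one weight per connected unordered pair) whose expansion
satisfies the constraints by construction.  The explicit ``B``/``E`` system
is kept as the ground-truth validator for every emitted matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import StructurePattern, WeightedNetwork

__all__ = [
    "EqualitySystem",
    "FreeParameterization",
    "build_equality_system",
    "satisfies",
    "free_parameterization",
]


@dataclass(frozen=True)
class EqualitySystem:
    """The boundary-condition system ``B @ vec(A) = E`` (row-major vec)."""

    B: np.ndarray
    E: np.ndarray
    row_kinds: tuple[str, ...]  # per row: diagonal | disconnection | symmetry | empty
    n: int


def build_equality_system(pattern: StructurePattern) -> EqualitySystem:
    """Construct the equality constraints for a structure pattern.

    Produces ``n`` diagonal rows, two rows per disconnected pair, and — when
    the pattern is symmetric — one symmetry row per connected unordered pair.
    All other rows are empty, so the system has at most n^2 equations in n^2
    unknowns.
    """
    n = pattern.n
    m = n * n
    B = np.zeros((m, m))
    E = np.zeros(m)
    kinds = ["empty"] * m

    for i in range(n):
        k = i * n + i
        B[k, k] = 1.0  # a_ii = 0
        kinds[k] = "diagonal"

    for i, j in sorted(pattern.disconnected):
        for k in (i * n + j, j * n + i):
            B[k, k] = 1.0  # a_ij = 0 and a_ji = 0
            kinds[k] = "disconnection"

    if pattern.symmetric:
        for i, j in pattern.connected_pairs():
            k = i * n + j
            B[k, i * n + j] = 1.0
            B[k, j * n + i] = -1.0  # a_ij - a_ji = 0
            kinds[k] = "symmetry"

    return EqualitySystem(B=B, E=E, row_kinds=tuple(kinds), n=n)


def satisfies(system: EqualitySystem, net: WeightedNetwork, tol: float = 1e-9) -> bool:
    """True iff ``max|B @ vec(A) - E| <= tol`` (row-major vectorization)."""
    if net.n != system.n:
        raise ValueError(f"system built for n={system.n}, network has n={net.n}")
    a = net.weights.reshape(-1)
    return bool(np.max(np.abs(system.B @ a - system.E)) <= tol)


@dataclass(frozen=True)
class FreeParameterization:
    """Bijection between constraint-satisfying matrices and free weights.

    For a symmetric pattern the free weights are the upper-triangle connected
    pairs; expanding them fills both ``a_ij`` and ``a_ji``, leaves the
    diagonal and disconnected pairs at exactly zero, and therefore satisfies
    the equality system by construction.
    """

    pattern: StructurePattern
    pairs: tuple[tuple[int, int], ...]

    @property
    def n_free(self) -> int:
        return len(self.pairs)

    def expand(self, free: np.ndarray) -> np.ndarray:
        """Free weight vector -> full conforming weight matrix."""
        free = np.asarray(free, dtype=float)
        if free.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free weights, got shape {free.shape}")
        w = np.zeros((self.pattern.n, self.pattern.n))
        idx = np.array(self.pairs, dtype=int).reshape(-1, 2)
        w[idx[:, 0], idx[:, 1]] = free
        w[idx[:, 1], idx[:, 0]] = free
        return w

    def reduce(self, weights: np.ndarray) -> np.ndarray:
        """Full weight matrix -> free weight vector (upper-triangle reads)."""
        w = np.asarray(weights, dtype=float)
        return np.array([w[i, j] for i, j in self.pairs])

    def network(self, free: np.ndarray) -> WeightedNetwork:
        return WeightedNetwork(self.expand(free), self.pattern)


def free_parameterization(pattern: StructurePattern) -> FreeParameterization:
    """Index map from free weights to conforming matrices.

    Only symmetric patterns admit the pairwise reduction used here.
    """
    if not pattern.symmetric:
        raise ValueError("free parameterization is defined for symmetric patterns only")
    return FreeParameterization(pattern=pattern, pairs=tuple(pattern.connected_pairs()))
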
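"""Analytic oracle networks and random instances for tests and examples.

The closed-form families double as independent checks on the eigensolver:

* complete uniform: ``r = (n-1) w``, uniform eigenvector, ``v = 0``;
* ring uniform:     ``r = 2 w``,     uniform eigenvector, ``v = 0``;
* star uniform:     ``r = w sqrt(n-1)``, hub score ``sqrt(1/2)``, each leaf
  ``sqrt(1 / (2 (n-1)))`` under unit Euclidean norm.

All fixtures are generated programmatically; nothing is stored on disk.
"""

from __future__ import annotations

import numpy as np

from .constraints import free_parameterization
from .errors import DisconnectedNetworkError
from .network import StructurePattern, WeightedNetwork

__all__ = ["complete_uniform", "ring_uniform", "star_uniform", "random_conforming"]


def complete_uniform(n: int, w: float) -> WeightedNetwork:
    """Complete network, every off-diagonal weight equal to ``w``."""
    if n < 2 or w <= 0:
        raise ValueError("complete_uniform requires n >= 2 and w > 0")
    mat = np.full((n, n), float(w))
    np.fill_diagonal(mat, 0.0)
    return WeightedNetwork.from_matrix(mat)


def ring_uniform(n: int, w: float) -> WeightedNetwork:
    """Cycle on ``n`` nodes, uniform weight ``w``; spectral radius ``2w``."""
    if n < 3 or w <= 0:
        raise ValueError("ring_uniform requires n >= 3 and w > 0")
    mat = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        mat[i, j] = mat[j, i] = float(w)
    disconnected = frozenset(
        (i, j) for i in range(n) for j in range(i + 1, n) if mat[i, j] == 0.0
    )
    return WeightedNetwork(mat, StructurePattern(n, disconnected))


def star_uniform(n: int, w: float) -> WeightedNetwork:
    """Star with hub node 0 and ``n - 1`` leaves, uniform weight ``w``."""
    if n < 3 or w <= 0:
        raise ValueError("star_uniform requires n >= 3 and w > 0")
    mat = np.zeros((n, n))
    mat[0, 1:] = mat[1:, 0] = float(w)
    disconnected = frozenset((i, j) for i in range(1, n) for j in range(i + 1, n))
    return WeightedNetwork(mat, StructurePattern(n, disconnected))


def random_conforming(
    n: int,
    w_min: float,
    w_max: float,
    seed: int,
    pattern: StructurePattern | None = None,
) -> WeightedNetwork:
    """Random connected network conforming to ``pattern``.

    Free weights are i.i.d. uniform on ``[w_min, w_max]``; deterministic per
    seed.  Raises if the pattern itself disconnects the graph.
    """
    if not (0 < w_min <= w_max):
        raise ValueError(f"need 0 < w_min <= w_max, got [{w_min}, {w_max}]")
    if pattern is None:
        pattern = StructurePattern(n)
    elif pattern.n != n:
        raise ValueError(f"pattern n={pattern.n} does not match n={n}")
    fp = free_parameterization(pattern)
    rng = np.random.default_rng(seed)
    net = fp.network(rng.uniform(w_min, w_max, size=fp.n_free))
    if not net.is_connected():
        raise DisconnectedNetworkError("structure pattern disconnects the network")
    return net
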
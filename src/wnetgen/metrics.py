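"""Spectral network metrics.

Three metrics summarize a weighted network hierarchically:

* the **spectral radius** ``r``, the largest eigenvalue of the adjacency
  matrix — a proxy of overall network connectivity;
* the **variance** ``v`` of the elements of the dominant (Perron)
  eigenvector — heterogeneity of node contributions to connectivity;
* the **skewness** ``s`` of those elements — the balance of highly versus
  weakly contributing nodes.

The dominant eigenvector is normalized to unit Euclidean norm with
nonnegative orientation, which Perron–Frobenius theory makes unique for
connected (irreducible) nonnegative matrices.  Variance and skewness are
population moments (divide by ``n``), and the skewness is evaluated through
its raw-moment expansion

    s = (mean(x^3) - 3*mean(x)*v - mean(x)^3) / v^(3/2),

algebraically equal to the third central moment over ``v^(3/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DisconnectedNetworkError, InvalidNetworkError, UndefinedSkewnessError
from .network import WeightedNetwork

__all__ = [
    "SpectralSummary",
    "spectral_radius",
    "dominant_eigenvector",
    "eigvec_variance",
    "eigvec_skewness",
    "summarize",
]

#: Variance below this is treated as exactly zero (homogeneous eigenvector).
_VAR_EPS = 1e-14


@dataclass(frozen=True)
class SpectralSummary:
    """Spectral radius plus moment summary of the dominant eigenvector.

    ``s`` is ``None`` when the eigenvector is homogeneous (``v == 0``),
    where skewness is undefined.
    """

    r: float
    eigenvector: np.ndarray
    mean: float
    v: float
    s: float | None


def spectral_radius(net: WeightedNetwork) -> float:
    """Largest eigenvalue of the weight matrix.

    For a symmetric nonnegative matrix this is real and nonnegative.
    """
    w = net.weights
    if net.pattern.symmetric:
        return float(scipy.linalg.eigvalsh(w, subset_by_index=(net.n - 1, net.n - 1))[0])
    eigvals = np.linalg.eigvals(w)
    return float(eigvals[np.argmax(eigvals.real)].real)


def dominant_eigenvector(net: WeightedNetwork) -> np.ndarray:
    """Perron eigenvector, unit Euclidean norm, all elements >= 0.

    Raises
    ------
    DisconnectedNetworkError
        If the nonzero pattern is not connected: the dominant eigenvector is
        then not unique / not strictly positive (Perron–Frobenius requires an
        irreducible matrix).
    """
    if not net.pattern.symmetric:
        raise InvalidNetworkError("dominant_eigenvector requires a symmetric network")
    if not net.is_connected():
        raise DisconnectedNetworkError(
            "dominant eigenvector not unique / not strictly positive: "
            "the network's nonzero pattern is disconnected"
        )
    _, vec = scipy.linalg.eigh(net.weights, subset_by_index=(net.n - 1, net.n - 1))
    x = vec[:, 0]
    if x.sum() < 0:
        x = -x
    # Perron vector is strictly positive; flush eigensolver round-off.
    return np.maximum(x, 0.0)


def eigvec_variance(x: np.ndarray) -> float:
    """Population variance (1/n) of the vector elements."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("variance of an empty vector is undefined")
    return float(np.mean((x - x.mean()) ** 2))


def eigvec_skewness(x: np.ndarray) -> float:
    """Population skewness via the raw-moment expansion.

    Raises
    ------
    UndefinedSkewnessError
        If the elements are all equal (variance zero).
    """
    x = np.asarray(x, dtype=float)
    v = eigvec_variance(x)
    if v <= _VAR_EPS:
        raise UndefinedSkewnessError("skewness undefined for homogeneous vector (v = 0)")
    m = float(x.mean())
    return float((np.mean(x**3) - 3.0 * m * v - m**3) / v**1.5)


def summarize(net: WeightedNetwork) -> SpectralSummary:
    """Bundle (r, x, mean, v, s) for a connected network.

    Skewness is reported as ``None`` when the eigenvector is homogeneous.
    """
    x = dominant_eigenvector(net)
    r = spectral_radius(net)
    v = eigvec_variance(x)
    if v <= _VAR_EPS:
        s: float | None = None
        v = 0.0
    else:
        s = eigvec_skewness(x)
    return SpectralSummary(r=r, eigenvector=x, mean=float(x.mean()), v=v, s=s)
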
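"""Weighted-network generation by constrained minimization with hill-climb restarts.

The generator searches for a symmetric, zero-diagonal, nonnegative weight
matrix whose spectral radius ``r`` and dominant-eigenvector variance ``v``
and skewness ``s`` match user targets ``(r*, v*, s*)``.  It minimizes the
weighted sum of squared metric differences

    J(A) = w1 (r* - r0)^2 + w2 (v* - v0)^2 + w3 (s* - s0)^2

over the free edge weights (the structural equality constraints — zero
diagonal, symmetry, forced disconnections — are eliminated by construction).
The outer loop is a hill climb: after each inner minimization the per-metric
differences are compared with a tolerance; on failure one randomly chosen
edge-weight pair is redrawn uniformly within the weight box and the
minimization restarts from the perturbed matrix.

The weight box ``[w_min, w_max]`` is the *randomization range*: the initial
matrix and every perturbation draw from it.  The minimization itself keeps
weights positive (a tiny connectivity floor preserves irreducibility) but by
default lets them leave the box — for some target combinations the optimum
genuinely lies outside it (e.g. strongly negative skewness at moderate
variance requires some weights below the randomization minimum, because a
complete graph with every weight >= w_min bounds the Perron elements below
by ``sum(x) * w_min / (r + w_min)``).  Pass ``hard_bounds=True`` to clamp
the minimization to the box as well.

The inner solver is deterministic bound-constrained quasi-Newton (L-BFGS-B)
with analytic gradients.  For a simple top eigenvalue of a symmetric matrix,

    dr/da_ij = 2 x_i x_j           (i < j, symmetric pair),
    dx/da_ij = sum_k  (x_k[i] x[j] + x_k[j] x[i]) / (r - l_k)  x_k,

summing over the non-dominant eigenpairs (l_k, x_k); the moment gradients
follow by the chain rule.  Connectedness (hence a simple Perron eigenvalue)
is preserved throughout because free weights are bounded below by
``w_min > 0``: disconnection is expressed only through the structure
pattern, never by driving a weight to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from . import feasibility
from .constraints import FreeParameterization, free_parameterization
from .errors import CriteriaError, UndefinedSkewnessError
from .metrics import SpectralSummary, summarize
from .network import StructurePattern, WeightedNetwork

__all__ = [
    "GenerationCriteria",
    "GenerationResult",
    "TrajectoryPoint",
    "random_initial_matrix",
    "objective",
    "minimize_step",
    "perturb",
    "metric_differences",
    "generate",
]

logger = logging.getLogger(__name__)

#: Targets with magnitude at or below this use absolute (not relative)
#: differences in the convergence check; it equals the default tolerance, so
#: "converged" means the same discrepancy scale for relative and absolute
#: metrics.
ABS_FALLBACK = 1e-2

#: Floor on target magnitudes in the default objective weights
#: w_k = 1 / max(target_k, OMEGA_FLOOR)^2.  Tied to the absolute-tolerance
#: scale so that each metric term contributes O(1) to the objective when the
#: metric sits at its tolerance boundary; a much smaller floor would let a
#: zero target dominate the objective by many orders of magnitude.
OMEGA_FLOOR = 1e-2

_MONOTONIC_SLACK = 1e-9  # solver noise margin on the descent contract


@dataclass(frozen=True)
class GenerationCriteria:
    """Targets, weights, bounds and budgets for one generation run.

    Parameters
    ----------
    n:
        Node count.
    r_star, v_star, s_star:
        Target spectral radius, eigenvector variance and skewness.
        ``s_star=None`` leaves skewness unconstrained.
    omega:
        Objective weights (w1, w2, w3).  ``None`` selects scale-normalized
        defaults ``1 / max(|target|, OMEGA_FLOOR)^2`` so that targets of very
        different magnitude (r* ~ 20-80 vs v* ~ 0.005) contribute comparably.
    w_min, w_max:
        Randomization range for nonzero edge weights (initial matrix and
        perturbation draws); ``w_min > 0`` keeps the network connected.
    hard_bounds:
        When true, the inner minimization is also clamped to
        ``[w_min, w_max]``; by default it may move weights outside the
        randomization range (they stay strictly positive).
    tol:
        Per-metric convergence tolerance — relative for targets larger in
        magnitude than `ABS_FALLBACK`, absolute otherwise.
    max_outer:
        Cap on hill-climb perturbations.
    max_inner:
        Iteration cap for each inner minimization.
    seed:
        Seed for the initial matrix and the perturbation draws.
    pattern:
        Structure pattern; ``None`` means fully connected symmetric.
    """

    n: int
    r_star: float
    v_star: float
    s_star: float | None = None
    omega: tuple[float, float, float] | None = None
    w_min: float = 1.0
    w_max: float = 50.0
    hard_bounds: bool = False
    tol: float = 0.01
    max_outer: int = 500
    max_inner: int = 1000
    seed: int = 0
    pattern: StructurePattern | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"generation requires n >= 3, got n={self.n}")
        if self.r_star <= 0:
            raise ValueError(f"spectral-radius target must be positive, got {self.r_star}")
        if self.v_star < 0:
            raise ValueError(f"variance target must be nonnegative, got {self.v_star}")
        if not (0 < self.w_min <= self.w_max):
            raise ValueError(
                f"weight bounds must satisfy 0 < w_min <= w_max, got [{self.w_min}, {self.w_max}]"
            )
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.omega is not None:
            if len(self.omega) != 3 or any(w < 0 for w in self.omega):
                raise ValueError("omega must be three nonnegative weights")
            if all(w == 0 for w in self.omega):
                raise ValueError("omega must not be all zero")
        if self.pattern is None:
            object.__setattr__(self, "pattern", StructurePattern(self.n))
        elif self.pattern.n != self.n:
            raise ValueError(f"pattern n={self.pattern.n} does not match criteria n={self.n}")
        elif not self.pattern.symmetric:
            raise ValueError("generation is specified for symmetric patterns only")

    def resolved_omega(self) -> tuple[float, float, float]:
        """Objective weights, substituting the scale-normalized default."""
        if self.omega is not None:
            return tuple(float(w) for w in self.omega)  # type: ignore[return-value]
        w1 = 1.0 / max(abs(self.r_star), OMEGA_FLOOR) ** 2
        w2 = 1.0 / max(abs(self.v_star), OMEGA_FLOOR) ** 2
        w3 = (
            1.0 / max(abs(self.s_star), OMEGA_FLOOR) ** 2
            if self.s_star is not None
            else 0.0
        )
        return (w1, w2, w3)


@dataclass(frozen=True)
class TrajectoryPoint:
    """One outer-loop record: objective and per-metric differences."""

    iteration: int
    objective: float
    dr: float
    dv: float
    ds: float


@dataclass(frozen=True)
class GenerationResult:
    network: WeightedNetwork
    achieved: SpectralSummary
    converged: bool
    outer_iterations: int
    trajectory: tuple[TrajectoryPoint, ...] = field(repr=False)


def _validate_or_raise(criteria: GenerationCriteria) -> None:
    violations = feasibility.validate(criteria)
    if violations:
        raise CriteriaError("; ".join(violations))
    pattern_net = WeightedNetwork(
        free_parameterization(criteria.pattern).expand(
            np.ones(len(criteria.pattern.connected_pairs()))
        ),
        criteria.pattern,
    )
    if not pattern_net.is_connected():
        raise CriteriaError("structure pattern disconnects the network")


def random_initial_matrix(
    criteria: GenerationCriteria, rng: np.random.Generator
) -> WeightedNetwork:
    """Random conforming start: free weights i.i.d. uniform on [w_min, w_max]."""
    fp = free_parameterization(criteria.pattern)
    free = rng.uniform(criteria.w_min, criteria.w_max, size=fp.n_free)
    return fp.network(free)


def metric_differences(
    achieved: SpectralSummary, criteria: GenerationCriteria
) -> tuple[float, float, float]:
    """Per-metric discrepancy between achieved and target values.

    Relative (``|target - achieved| / |target|``) for targets with magnitude
    above `ABS_FALLBACK`, absolute otherwise.  The skewness slot is 0 when no
    skewness target is set, and infinite when a target is set but the
    achieved eigenvector is homogeneous (skewness undefined).
    """

    def diff(target: float, value: float) -> float:
        d = abs(target - value)
        return d / abs(target) if abs(target) > ABS_FALLBACK else d

    dr = diff(criteria.r_star, achieved.r)
    dv = diff(criteria.v_star, achieved.v)
    if criteria.s_star is None:
        ds = 0.0
    elif achieved.s is None:
        ds = math.inf
    else:
        ds = diff(criteria.s_star, achieved.s)
    return (dr, dv, ds)


def _objective_and_grad(
    free: np.ndarray,
    fp: FreeParameterization,
    criteria: GenerationCriteria,
) -> tuple[float, np.ndarray]:
    """Objective J and its gradient w.r.t. the free weights.

    Uses first-order perturbation of the simple top eigenpair of the
    symmetric weight matrix; near-degenerate spectral gaps are floored to
    keep the gradient finite (the hill-climb recovers from the resulting
    inexactness).
    """
    w1, w2, w3 = criteria.resolved_omega()
    n = fp.pattern.n
    A = fp.expand(free)
    lam, V = scipy.linalg.eigh(A)
    r = lam[-1]
    x = V[:, -1].copy()
    if x.sum() < 0:
        x = -x
        V = V.copy()
        V[:, -1] = x

    m = x.mean()
    v = float(np.mean(x**2) - m**2)
    if w3 > 0 and v <= 1e-16:
        raise UndefinedSkewnessError(
            "objective undefined: homogeneous eigenvector (v = 0) with a skewness target"
        )

    J = w1 * (criteria.r_star - r) ** 2 + w2 * (criteria.v_star - v) ** 2
    if w3 > 0:
        num = float(np.mean(x**3) - 3.0 * m * v - m**3)
        s = num / v**1.5
        J += w3 * (criteria.s_star - s) ** 2

    pairs = np.asarray(fp.pairs, dtype=int).reshape(-1, 2)
    ii, jj = pairs[:, 0], pairs[:, 1]

    # dr/dw_p for the symmetric pair (i, j)
    dr_dw = 2.0 * x[ii] * x[jj]

    # dx/dw_p through the non-dominant eigenpairs
    gap = r - lam[:-1]
    gap = np.maximum(gap, 1e-10 * max(1.0, abs(r)))
    Vk = V[:, :-1]
    coef = (x[jj, None] * Vk[ii, :] + x[ii, None] * Vk[jj, :]) / gap[None, :]
    dX_dw = coef @ Vk.T  # (n_free, n)

    dv_dx = 2.0 * (x - m) / n
    grad = -2.0 * w1 * (criteria.r_star - r) * dr_dw
    grad += -2.0 * w2 * (criteria.v_star - v) * (dX_dw @ dv_dx)
    if w3 > 0:
        dnum_dx = 3.0 * x**2 / n - 3.0 * (v / n + m * dv_dx) - 3.0 * m**2 / n
        ds_dx = dnum_dx / v**1.5 - 1.5 * s * dv_dx / v
        grad += -2.0 * w3 * (criteria.s_star - s) * (dX_dw @ ds_dx)
    return float(J), grad


def objective(net: WeightedNetwork, criteria: GenerationCriteria) -> float:
    """Weighted sum of squared metric differences for a network.

    Raises
    ------
    UndefinedSkewnessError
        If a skewness target carries positive weight but the network's
        dominant eigenvector is homogeneous.
    """
    w1, w2, w3 = criteria.resolved_omega()
    summary = summarize(net)
    J = w1 * (criteria.r_star - summary.r) ** 2 + w2 * (criteria.v_star - summary.v) ** 2
    if w3 > 0:
        if summary.s is None:
            raise UndefinedSkewnessError(
                "objective undefined: homogeneous eigenvector (v = 0) with a skewness target"
            )
        J += w3 * (criteria.s_star - summary.s) ** 2
    return float(J)


def minimize_step(start: WeightedNetwork, criteria: GenerationCriteria) -> WeightedNetwork:
    """One inner minimization from ``start``; never returns a worse matrix.

    Bound-constrained quasi-Newton descent over the free weights.  On solver
    failure, or if the proposal does not honor the monotonicity contract
    (objective not increased beyond a small solver-noise margin), ``start``
    is returned unchanged and the outer loop proceeds by perturbation.
    """
    fp = free_parameterization(criteria.pattern)
    x0 = fp.reduce(start.weights)
    if criteria.hard_bounds:
        lo, hi = criteria.w_min, criteria.w_max
    else:
        lo, hi = min(criteria.w_min, 1e-6), np.inf  # connectivity floor only
    try:
        f0, _ = _objective_and_grad(x0, fp, criteria)
        res = scipy.optimize.minimize(
            _objective_and_grad,
            np.clip(x0, lo, hi),
            args=(fp, criteria),
            jac=True,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * fp.n_free,
            options={"maxiter": criteria.max_inner, "ftol": 1e-15, "gtol": 1e-12},
        )
    except UndefinedSkewnessError:
        logger.warning("inner solver hit an undefined-skewness point; keeping start")
        return start
    if res.fun <= f0 + _MONOTONIC_SLACK:
        return fp.network(np.clip(res.x, lo, hi))
    logger.warning("inner solver returned a worse point (%.3g > %.3g); keeping start", res.fun, f0)
    return start


def perturb(
    net: WeightedNetwork, criteria: GenerationCriteria, rng: np.random.Generator
) -> WeightedNetwork:
    """Redraw one randomly chosen connected weight pair uniformly in the box.

    Exactly one unordered pair (i, j) changes; both ``a_ij`` and ``a_ji`` are
    set to the same fresh uniform draw so symmetry is preserved.
    """
    pairs = net.pattern.connected_pairs()
    if not pairs:
        raise ValueError("network has no connected pairs to perturb")
    i, j = pairs[rng.integers(len(pairs))]
    w = net.weights.copy()
    w[i, j] = w[j, i] = rng.uniform(criteria.w_min, criteria.w_max)
    return net.with_weights(w)


def generate(
    criteria: GenerationCriteria, start: WeightedNetwork | None = None
) -> GenerationResult:
    """Run the full perturb-and-descend loop.

    Each outer iteration minimizes the objective from the current matrix,
    measures the achieved metrics, and stops when every per-metric difference
    falls at or below ``criteria.tol``; otherwise one weight pair is
    perturbed and the minimization restarts.  At most ``max_outer``
    perturbations are attempted; non-convergence is a reported outcome, not
    an error.  Identical (criteria, seed, start) reproduce the run exactly.

    Raises
    ------
    CriteriaError
        If the targets violate the feasibility bounds (e.g. a skewness
        target with ``v* = 0``, or ``|s*|`` beyond the extremal bound) or the
        pattern disconnects the network.
    """
    _validate_or_raise(criteria)
    rng = np.random.default_rng(criteria.seed)
    net = start if start is not None else random_initial_matrix(criteria, rng)

    trajectory: list[TrajectoryPoint] = []
    converged = False
    outer = 0
    while True:
        net = minimize_step(net, criteria)
        achieved = summarize(net)
        dr, dv, ds = metric_differences(achieved, criteria)
        try:
            J = objective(net, criteria)
        except UndefinedSkewnessError:
            J = math.inf
        trajectory.append(TrajectoryPoint(outer, J, dr, dv, ds))
        if max(dr, dv, ds) <= criteria.tol:
            converged = True
            break
        if outer >= criteria.max_outer:
            break
        net = perturb(net, criteria, rng)
        outer += 1

    return GenerationResult(
        network=net,
        achieved=summarize(net),
        converged=converged,
        outer_iterations=outer,
        trajectory=tuple(trajectory),
    )
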
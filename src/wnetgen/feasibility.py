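"""Feasibility bounds on eigenvector moments and convergence mapping.

For a unit-Euclidean-norm nonnegative vector of length ``n`` the population
variance is ``v = 1/n - mean(x)^2`` with ``mean(x)`` in ``[1/n, 1/sqrt(n)]``,
so the attainable variance is bounded by

    v_max = (n - 1) / n^2        (mean at its minimum: one-hot vector),

and the population skewness of any ``n`` numbers is bounded in magnitude by
the classical two-point extremal

    s_bound = (n - 2) / sqrt(n - 1).

These closed forms are derived here from the unit-norm normalization
convention, not transcribed from elsewhere; the test-suite corroborates them
empirically on every generated network.

`feasibility_map` replays the generator over a (v*, s*) grid at fixed
spectral-radius target and records which points converge — an empirical
picture of the attainable region for a given node count and weight box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .generator import GenerationCriteria

__all__ = [
    "FeasibilityBounds",
    "ConvergenceMap",
    "bounds",
    "validate",
    "feasibility_map",
]

#: Absolute slack beyond the analytic bounds accepted by `validate`.  Targets
#: are typically stated at finite printed precision; a target that exceeds a
#: bound by less than half a unit in its last printed decimal is treated as
#: sitting *at* the bound rather than beyond it.
BOUND_SLACK = 5e-3


@dataclass(frozen=True)
class FeasibilityBounds:
    """Attainable-moment bounds for unit-norm nonnegative eigenvectors."""

    n: int
    v_max: float
    s_bound: float


@dataclass(frozen=True)
class MapRecord:
    v_star: float
    s_star: float
    converged: bool
    violations: tuple[str, ...]
    r_achieved: float | None
    v_achieved: float | None
    s_achieved: float | None


@dataclass(frozen=True)
class ConvergenceMap:
    """Convergence records over a (v*, s*) grid at fixed r* and weight box."""

    n: int
    r_star: float
    w_min: float
    w_max: float
    grid: tuple[MapRecord, ...]

    def to_rows(self) -> list[dict]:
        return [
            {
                "v_star": rec.v_star,
                "s_star": rec.s_star,
                "converged": rec.converged,
                "r_achieved": rec.r_achieved,
                "v_achieved": rec.v_achieved,
                "s_achieved": rec.s_achieved,
            }
            for rec in self.grid
        ]


def bounds(n: int) -> FeasibilityBounds:
    """Closed-form bounds on eigenvector variance and skewness.

    Requires ``n >= 3``: with two nodes the skewness of the eigenvector is
    degenerate (any two numbers have |skewness| 0 or undefined).
    """
    if n < 3:
        raise ValueError(f"feasibility bounds require n >= 3, got n={n}")
    return FeasibilityBounds(
        n=n,
        v_max=(n - 1) / n**2,
        s_bound=(n - 2) / math.sqrt(n - 1),
    )


def validate(criteria: "GenerationCriteria") -> list[str]:
    """Check targets against the attainable bounds; return violations.

    Empty list iff ``v*`` lies in ``[0, v_max]``, ``|s*| <= s_bound`` and no
    skewness target accompanies ``v* = 0``.  Each violation names the bound
    it breaks.  Comparisons carry `BOUND_SLACK` absolute slack so that
    targets printed at finite precision and sitting on a bound still pass.
    """
    b = bounds(criteria.n)
    violations: list[str] = []
    if criteria.v_star < 0:
        violations.append(f"variance target {criteria.v_star} is negative")
    elif criteria.v_star > b.v_max + BOUND_SLACK:
        violations.append(
            f"variance target {criteria.v_star} exceeds the attainable maximum "
            f"(n-1)/n^2 = {b.v_max:.6g} for n={criteria.n}"
        )
    if criteria.s_star is not None:
        if criteria.v_star == 0.0:
            violations.append(
                "skewness target is inconsistent with variance target 0 "
                "(skewness undefined for a homogeneous eigenvector)"
            )
        if abs(criteria.s_star) > b.s_bound + BOUND_SLACK:
            violations.append(
                f"skewness target {criteria.s_star} exceeds the extremal bound "
                f"(n-2)/sqrt(n-1) = {b.s_bound:.6g} for n={criteria.n}"
            )
    return violations


def feasibility_map(
    n: int,
    r_star: float,
    v_grid: Sequence[float],
    s_grid: Sequence[float],
    *,
    w_min: float = 1.0,
    w_max: float = 50.0,
    tol: float = 0.01,
    max_outer: int = 500,
    seed: int = 0,
) -> ConvergenceMap:
    """Run the generator at every (v*, s*) grid point and record convergence.

    Each grid point gets its own deterministic seed derived from ``seed`` and
    the point's index, so the whole map reproduces under a fixed seed.
    Points whose targets violate the feasibility bounds are recorded as
    non-converged without attempting generation.
    """
    from .generator import GenerationCriteria, generate

    if len(v_grid) == 0 or len(s_grid) == 0:
        raise ValueError("v_grid and s_grid must be non-empty")

    records: list[MapRecord] = []
    for idx, (v_star, s_star) in enumerate(
        (float(v), float(s)) for v in v_grid for s in s_grid
    ):
        point_seed = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)
        try:
            criteria = GenerationCriteria(
                n=n,
                r_star=r_star,
                v_star=v_star,
                s_star=s_star,
                w_min=w_min,
                w_max=w_max,
                tol=tol,
                max_outer=max_outer,
                seed=point_seed,
            )
            violations = tuple(validate(criteria))
        except ValueError as exc:
            violations = (str(exc),)
        if violations:
            records.append(
                MapRecord(v_star, s_star, False, violations, None, None, None)
            )
            continue
        result = generate(criteria)
        ach = result.achieved
        records.append(
            MapRecord(
                v_star,
                s_star,
                result.converged,
                (),
                ach.r,
                ach.v,
                ach.s if ach.s is not None else math.nan,
            )
        )
    return ConvergenceMap(n=n, r_star=r_star, w_min=w_min, w_max=w_max, grid=tuple(records))
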
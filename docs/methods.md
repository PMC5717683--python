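# Methods

## Model

A weighted network on `n` nodes is a square matrix `A` with `a_ii = 0`,
`a_ij ≥ 0`, and (by default) `a_ij = a_ji` — in the motivating habitat-graph
setting, `a_ij` is the cost of species movement between patches `i` and `j`
(the examples use km, but the units are the user's). Three metrics summarize
it hierarchically:

1. **Spectral radius** `r = max{λ₁,…,λₙ}`. For a connected symmetric
   nonnegative matrix this is the simple Perron eigenvalue, real and
   nonnegative.
2. **Eigenvector variance** `v`: population variance (divide by `n`) of the
   elements of the dominant eigenvector `x_r`.
3. **Eigenvector skewness** `s`: population skewness of those elements,
   evaluated through the raw-moment expansion
   `s = (mean(x³) − 3·mean(x)·v − mean(x)³) / v^{3/2}`, which is
   algebraically identical to the third central moment over `v^{3/2}`.

**Eigenvector normalization.** `v` and `s` are not invariant to the
eigenvector's normalization, so a convention is required: `x_r` is scaled to
unit Euclidean norm with nonnegative orientation. Perron–Frobenius theory
makes this vector unique and strictly positive whenever the nonzero pattern
of `A` is connected (irreducible). Disconnected patterns are rejected rather
than given an arbitrary eigenvector: the dominant eigenvalue can then have
multiplicity above one and the metrics would depend on solver internals.
Under this convention `mean(x²) = 1/n` exactly, which gives the closed-form
feasibility bounds below.

A homogeneous eigenvector (`v = 0`, e.g. any uniform-weight vertex-transitive
network) has undefined skewness; `summarize` reports `s = None` and criteria
that request a skewness together with `v* = 0` are rejected as inconsistent.

**Numerical note.** The raw-moment skewness expansion loses roughly 1e-8 of
absolute accuracy through cancellation when the eigenvector spread is tiny
(`v ≲ 1e-6`); the variance floor `1e-14` below which skewness is declared
undefined keeps the expression well defined, and the test suite checks the
expansion against the direct central-moment formula away from that regime.

## Feasibility bounds

For any unit-norm nonnegative vector, `v = 1/n − mean(x)²` with
`mean(x) ∈ [1/n, 1/√n]`, so

* `v_max = (n−1)/n²` (attained by a one-hot vector), and
* `|s| ≤ (n−2)/√(n−1)`, the classical extremal skewness of `n` numbers
  (attained by two-point configurations with a single outlier).

These are derived from the normalization convention above, not transcribed
from elsewhere. `validate` accepts targets up to `0.005` beyond a bound:
targets are commonly stated at two- or three-decimal precision, and a value
that exceeds a bound by less than half a unit in its last printed decimal
(e.g. `s* = −1.79` against the n=6 bound `−4/√5 ≈ −1.78885`) denotes the
bound itself, not a point beyond it. The optimizer then converges onto the
boundary and the convergence check (below) absorbs the rounding gap. Every
generated network is additionally checked empirically against both bounds in
the test suite.

The bounds above are marginal. The attainable `(v, s)` *pairs* also depend
on `n`, on `r*`, and on how small weights may get (see the weight-box
discussion below); `feasibility_map` explores that region empirically by
running the generator over a `(v*, s*)` grid.

## The generator

Targets `(r*, v*, s*)` define the objective

    J(A) = ω₁ (r* − r₀)² + ω₂ (v* − v₀)² + ω₃ (s* − s₀)²,

minimized over the free edge weights. The structural rules are kept in two
forms: as the explicit equality system `B·vec(A) = E` (row-major
vectorization; one row per diagonal entry, two per forced-zero pair, one
symmetry row per connected pair; `E = 0`), used as a post-hoc validator at
tolerance 1e-9 on every emitted matrix — and as a *free parameterization*
(one scalar per connected unordered pair) that satisfies the system by
construction and is what the optimizer actually works in. The two describe
the identical feasible set; eliminating the constraints avoids solving an
`n²×n²` system inside every objective evaluation.

The loop:

1. draw a random conforming start (free weights i.i.d. uniform on
   `[w_min, w_max]`);
2. minimize `J` with deterministic bound-constrained L-BFGS-B
   (`ftol = 1e-15`, `gtol = 1e-12`, `max_inner = 1000` iterations), using
   analytic gradients: for a simple top eigenpair of a symmetric matrix,
   `dr/da_ij = 2 x_i x_j` and
   `dx/da_ij = Σ_k (x_k[i] x[j] + x_k[j] x[i]) / (r − λ_k) · x_k` over the
   non-dominant eigenpairs, with the moment gradients following by the
   chain rule. Spectral gaps below `1e-10·max(1, r)` are floored to keep
   the gradient finite. A step that would end worse than it started
   (beyond a 1e-9 noise margin) is discarded, so the objective is
   non-increasing within every inner step by contract;
3. compare each achieved metric with its target — relative difference for
   targets of magnitude above 0.01, absolute difference otherwise — and stop
   when all three fall at or below `tol` (default 0.01, i.e. 1% relative
   with a 0.01 absolute fallback for near-zero targets);
4. otherwise redraw one uniformly chosen connected weight pair (both
   `a_ij` and `a_ji`, jointly, to preserve symmetry) uniformly in
   `[w_min, w_max]` and go to 2, for at most `max_outer = 500`
   perturbations. Non-convergence is a reported outcome, not an exception.

Runs are fully deterministic given `(criteria, seed)`: the only random
draws are the initial matrix and the perturbations, both from one seeded
PCG64 generator, and the inner solver is deterministic.

### Objective weights

Defaults are scale-normalized, `ω_k = 1 / max(|target_k|, 0.01)²`, so a
spectral-radius target of 80 and a variance target of 0.005 contribute
comparably near convergence. The floor 0.01 matches the absolute-tolerance
scale: each metric's term is then O(1) when the metric sits at its
tolerance boundary. (A much smaller floor would let a zero skewness target
carry a weight of ~1e12 and dominate the objective by eight orders of
magnitude, which conditions the quasi-Newton step badly.) Users can pass
explicit `ω` to prioritize metrics differently.

### The weight box is a randomization range

`w_min` and `w_max` bound the *random draws* — the initial matrix and every
perturbation — but, by default, not the inner minimization, which enforces
only a tiny positive floor (`min(w_min, 1e-6)`) so that no weight can reach
exactly zero and disconnect the network. The distinction matters: on a
complete graph with every weight clamped at or above `w_min`, the Perron
elements obey `x_i ≥ Σx · w_min / (r + w_min)`, which bounds how asymmetric
the eigenvector can be. At `n = 10`, `r* = 20`, `w_min = 1`, the target pair
`(v*, s*) = (0.025, −0.5)` is provably outside that clamped region (the
most negative skewness compatible with the induced element floor is about
−0.2) yet is reached immediately once the minimizer may move individual
weights below 1. Since target combinations like this one are demonstrably
attainable and useful, the box is treated as the sampling range; pass
`hard_bounds=True` to restore a strict box when weights carry hard physical
limits, accepting the smaller feasible region that follows.

## What the random fixtures emulate — and what they do not

`fixtures.random_conforming` draws fully connected symmetric networks with
uniform weights, matching the generator's own initial conditions; the
closed-form families (complete, ring, star) supply analytic spectra that
act as independent oracles for the eigensolver. Self-consistency tests
(regenerate a network from its own measured metrics) show the algorithm
recovers *attainable* metric triples reliably — 40/40 in the shipped suite —
but none of this exercises empirical weight distributions (e.g. heavy-tailed
dispersal kernels), sparse large-`n` structures, or asymmetric flows, so
passing tests demonstrate correctness of the machinery, not coverage of any
particular empirical network class.

## Problem sizes and budgets

All shipped examples and tests use `n = 5–10` with dense eigendecompositions
(`scipy.linalg.eigh`); a generation run at these sizes takes well under a
second, and the whole test suite a few tens of seconds. The dense solver is
the deliberate choice up to a few hundred nodes — the regime the method is
intended for; no sparse/iterative path is provided.

## Known limitations

* Convergence is to a local minimum of `J`; the perturbation loop provides
  restarts but no global guarantee, and no multi-start or annealing schedule
  is attempted beyond the single perturb-and-descend loop.
* Generation is specified for symmetric patterns only; the constraint
  builder supports asymmetric (unidirectional) patterns, but the generator
  and its tests do not cover them.
* Skewness follows the literal statistical convention of the formula: a
  single node with an unusually *high* connectivity score yields positive
  skew, a single unusually low one negative skew. Informal readings of
  eigenvector skewness sometimes invert this ("more highly connected nodes
  ⇒ positive"); the package implements only the formula and leaves the
  interpretation to the user.
* Binary (0/1) network generation with these criteria is a nonlinear integer
  problem and is out of scope.
* The equality system supports a nonzero right-hand side `E` structurally
  (e.g. pinning a specific weight), but all defined rules set `E = 0` and
  nonzero values are unexercised.
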
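"""Generation loop: initialization, objective, descent, perturbation, recovery."""

import math

import numpy as np
import pytest

from wnetgen import (
    GenerationCriteria,
    StructurePattern,
    build_equality_system,
    fixtures,
    generate,
    metric_differences,
    minimize_step,
    objective,
    perturb,
    random_initial_matrix,
    satisfies,
    summarize,
)
from wnetgen.constraints import free_parameterization
from wnetgen.errors import CriteriaError
from wnetgen.generator import _objective_and_grad


def criteria_from_network(net, **overrides):
    """Criteria whose targets are a network's own measured metrics."""
    s = summarize(net)
    kw = dict(n=net.n, r_star=s.r, v_star=s.v, s_star=s.s, pattern=net.pattern)
    kw.update(overrides)
    return GenerationCriteria(**kw)


class TestRandomInitialMatrix:
    def test_bounds_and_symmetry(self):
        crit = GenerationCriteria(n=6, r_star=80, v_star=0.026, seed=5)
        rng = np.random.default_rng(crit.seed)
        net = random_initial_matrix(crit, rng)
        free = free_parameterization(crit.pattern).reduce(net.weights)
        assert free.size == 15
        assert np.all((free >= crit.w_min) & (free <= crit.w_max))
        assert np.array_equal(net.weights, net.weights.T)

    def test_deterministic_per_seed(self):
        crit = GenerationCriteria(n=8, r_star=30, v_star=0.01, seed=9)
        a = random_initial_matrix(crit, np.random.default_rng(9))
        b = random_initial_matrix(crit, np.random.default_rng(9))
        assert np.array_equal(a.weights, b.weights)

    def test_uniform_law(self):
        crit = GenerationCriteria(n=6, r_star=80, v_star=0.026, w_min=1, w_max=50, seed=0)
        rng = np.random.default_rng(0)
        draws = np.concatenate(
            [free_parameterization(crit.pattern).reduce(random_initial_matrix(crit, rng).weights)
             for _ in range(100)]
        )
        se = (crit.w_max - crit.w_min) / math.sqrt(12 * draws.size)
        assert abs(draws.mean() - 25.5) <= 3 * se


class TestObjective:
    def test_zero_at_exact_targets(self):
        net = fixtures.random_conforming(8, 1, 50, seed=3)
        assert objective(net, criteria_from_network(net)) == pytest.approx(0.0, abs=1e-18)

    def test_pure_spectral_radius_term(self):
        net = fixtures.complete_uniform(6, 16)  # r0 = 80
        crit = GenerationCriteria(n=6, r_star=90, v_star=0.0, omega=(1, 0, 0))
        assert objective(net, crit) == pytest.approx(100.0, abs=1e-8)

    def test_recomposition_oracle(self):
        for seed in range(10):
            net = fixtures.random_conforming(6, 1, 50, seed=seed)
            crit = GenerationCriteria(
                n=6, r_star=40 + seed, v_star=0.01, s_star=0.2, omega=(0.3, 10.0, 2.0)
            )
            s = summarize(net)
            expected = (
                0.3 * (crit.r_star - s.r) ** 2
                + 10.0 * (crit.v_star - s.v) ** 2
                + 2.0 * (crit.s_star - s.s) ** 2
            )
            assert objective(net, crit) == pytest.approx(expected, abs=1e-12)

    def test_analytic_gradient_matches_finite_differences(self):
        crit = GenerationCriteria(n=6, r_star=65, v_star=0.0086, s_star=1.086)
        fp = free_parameterization(crit.pattern)
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 50, fp.n_free)
        _, grad = _objective_and_grad(x, fp, crit)
        h = 1e-6
        for k in range(fp.n_free):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            numeric = (
                _objective_and_grad(xp, fp, crit)[0] - _objective_and_grad(xm, fp, crit)[0]
            ) / (2 * h)
            assert grad[k] == pytest.approx(numeric, rel=1e-3, abs=1e-8)


class TestMetricDifferences:
    def test_exact_match_is_zero(self):
        net = fixtures.random_conforming(6, 1, 50, seed=1)
        assert metric_differences(summarize(net), criteria_from_network(net)) == (0, 0, 0)

    def test_relative_mode(self):
        net = fixtures.random_conforming(6, 1, 50, seed=1)
        crit = criteria_from_network(net)
        achieved = summarize(net)
        crit21 = GenerationCriteria(n=6, r_star=20, v_star=achieved.v, s_star=achieved.s)
        shifted = summarize(net.with_weights(net.weights * (21 / achieved.r)))
        dr, _, _ = metric_differences(shifted, crit21)
        assert dr == pytest.approx(0.05, abs=1e-12)

    def test_absolute_fallback_near_zero_target(self):
        net = fixtures.random_conforming(6, 1, 50, seed=1)
        achieved = summarize(net)
        crit = GenerationCriteria(n=6, r_star=achieved.r, v_star=achieved.v, s_star=0.0)
        _, _, ds = metric_differences(achieved, crit)
        assert ds == pytest.approx(abs(achieved.s), abs=1e-12)


class TestPerturb:
    def test_changes_exactly_one_symmetric_pair(self):
        crit = GenerationCriteria(n=6, r_star=80, v_star=0.026, seed=0)
        rng = np.random.default_rng(0)
        net = random_initial_matrix(crit, rng)
        for _ in range(10):
            new = perturb(net, crit, rng)
            delta = np.argwhere(new.weights != net.weights)
            assert len(delta) == 2
            (i1, j1), (i2, j2) = delta
            assert (i1, j1) == (j2, i2)
            assert np.array_equal(new.weights, new.weights.T)
            assert np.all(np.diagonal(new.weights) == 0)
            net = new

    def test_pair_selection_uniform(self):
        crit = GenerationCriteria(n=6, r_star=80, v_star=0.026, seed=0)
        rng = np.random.default_rng(1)
        net = random_initial_matrix(crit, rng)
        counts = {}
        for _ in range(10_000):
            new = perturb(net, crit, rng)
            i, j = np.argwhere(new.weights != net.weights)[0]
            counts[(min(i, j), max(i, j))] = counts.get((min(i, j), max(i, j)), 0) + 1
        p = 1 / 15
        se = math.sqrt(p * (1 - p) / 10_000)
        assert len(counts) == 15
        for pair_count in counts.values():
            assert abs(pair_count / 10_000 - p) <= 4 * se


class TestMinimizeStep:
    def test_already_optimal_start(self):
        net = fixtures.random_conforming(8, 1, 50, seed=21)
        crit = criteria_from_network(net)
        out = minimize_step(net, crit)
        assert objective(out, crit) <= 1e-9

    def test_descends_along_scaling_direction(self):
        net = fixtures.random_conforming(6, 1, 50, seed=4)
        r0 = summarize(net).r
        crit = GenerationCriteria(n=6, r_star=1.3 * r0, v_star=0.0, omega=(1, 0, 0))
        assert objective(minimize_step(net, crit), crit) < objective(net, crit)

    def test_never_increases_objective_and_stays_conforming(self):
        pattern_disc = frozenset([(0, 4), (2, 3)])
        for seed in range(25):
            net = fixtures.random_conforming(
                6, 1, 50, seed=seed,
                pattern=None if seed % 2 else StructurePattern(6, pattern_disc),
            )
            crit = GenerationCriteria(
                n=6, r_star=30.0, v_star=0.01, s_star=0.3, pattern=net.pattern, seed=seed
            )
            out = minimize_step(net, crit)
            assert objective(out, crit) <= objective(net, crit) + 1e-9
            system = build_equality_system(net.pattern)
            assert satisfies(system, out, tol=1e-9)


class TestGenerate:
    def test_zero_outer_iterations_from_optimal_start(self):
        net = fixtures.random_conforming(8, 1, 50, seed=33)
        result = generate(criteria_from_network(net, seed=1), start=net)
        assert result.converged
        assert result.outer_iterations == 0

    def test_parameter_recovery(self):
        converged = 0
        for seed in range(6):
            net = fixtures.random_conforming(6, 1, 50, seed=100 + seed)
            result = generate(criteria_from_network(net, seed=seed))
            converged += result.converged
            dr, dv, ds = metric_differences(result.achieved, criteria_from_network(net))
            if result.converged:
                assert max(dr, dv, ds) <= 0.01
        assert converged >= 5

    def test_infeasible_skewness_rejected(self):
        crit = GenerationCriteria(n=6, r_star=80, v_star=0.02, s_star=3.0)
        with pytest.raises(CriteriaError, match="extremal bound"):
            generate(crit)

    def test_skewness_with_zero_variance_rejected(self):
        crit = GenerationCriteria(n=6, r_star=80, v_star=0.0, s_star=1.0)
        with pytest.raises(CriteriaError, match="homogeneous"):
            generate(crit)

    def test_deterministic_under_fixed_seed(self):
        crit = GenerationCriteria(n=6, r_star=65, v_star=0.0086, s_star=1.086, seed=11)
        a, b = generate(crit), generate(crit)
        assert np.array_equal(a.network.weights, b.network.weights)
        assert a.trajectory == b.trajectory
        assert a.outer_iterations == b.outer_iterations

    def test_emitted_network_passes_constraints(self):
        crit = GenerationCriteria(n=6, r_star=40, v_star=0.01, s_star=0.5, seed=2)
        result = generate(crit)
        system = build_equality_system(crit.pattern)
        assert satisfies(system, result.network, tol=1e-9)

    def test_respects_disconnection_pattern(self):
        pattern = StructurePattern(6, frozenset([(0, 5), (1, 4)]))
        crit = GenerationCriteria(
            n=6, r_star=40, v_star=0.01, s_star=0.2, pattern=pattern, seed=3
        )
        result = generate(crit)
        assert result.network.weights[0, 5] == 0.0
        assert result.network.weights[4, 1] == 0.0
        assert satisfies(build_equality_system(pattern), result.network, tol=1e-9)

    def test_trajectory_records_every_outer_iteration(self):
        crit = GenerationCriteria(n=6, r_star=40, v_star=0.01, s_star=0.2, seed=8)
        result = generate(crit)
        assert len(result.trajectory) == result.outer_iterations + 1
        assert [p.iteration for p in result.trajectory] == list(
            range(result.outer_iterations + 1)
        )
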
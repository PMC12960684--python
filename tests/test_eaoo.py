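"""Unit and property tests for the oat-dispersal optimizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oatfusion import eaoo
from oatfusion.eaoo import (
    Bounds,
    DynamicParams,
    OptimizerConfig,
    Population,
    compute_dynamic_params,
    de_crossover,
    exploration_step,
    greedy_select,
    initialize_population,
    jumping_update,
    levy_sigma,
    levy_step,
    nonuniform_mutation,
    optimize,
    rolling_update,
)


def sphere(x):
    return float(np.sum(x**2))


def make_pop(positions, best, iteration=0):
    positions = np.asarray(positions, dtype=float)
    fitness = np.array([sphere(x) for x in positions])
    return Population(
        positions=positions,
        fitness=fitness,
        best_position=np.asarray(best, dtype=float),
        best_fitness=sphere(np.asarray(best, dtype=float)),
        iteration=iteration,
    )


class TestBoundsAndConfig:
    def test_bounds_reject_nonfinite_and_inverted(self):
        with pytest.raises(ValueError):
            Bounds(np.array([0.0, np.inf]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            Bounds(np.array([3.0]), np.array([1.0]))

    def test_config_defaults_and_validation(self):
        cfg = OptimizerConfig()
        assert (cfg.pop_size, cfg.max_iter) == (50, 100)
        assert (cfg.scale_factor, cfg.crossover_rate, cfg.mutation_prob) == (
            0.5,
            0.9,
            0.1,
        )
        assert cfg.levy_beta == 1.5
        cfg.validate()
        with pytest.raises(ValueError):
            OptimizerConfig(pop_size=3).validate()
        with pytest.raises(ValueError):
            OptimizerConfig(levy_beta=2.5).validate()
        with pytest.raises(ValueError):
            OptimizerConfig(gravity=0.0).validate()


class TestInitialization:
    def test_positions_inside_box_and_evaluated(self, rng):
        bounds = Bounds.cube(0.0, 1.0, 3)
        pop = initialize_population(
            bounds, OptimizerConfig(pop_size=4), rng, sphere
        )
        assert pop.positions.shape == (4, 3)
        assert np.all(pop.positions >= 0.0) and np.all(pop.positions <= 1.0)
        assert pop.best_fitness == pop.fitness.min()

    def test_degenerate_interval_collapses(self, rng):
        bounds = Bounds.cube(5.0, 5.0, 2)
        pop = initialize_population(
            bounds, OptimizerConfig(pop_size=4), rng, sphere
        )
        assert np.all(pop.positions == 5.0)

    def test_same_seed_is_bitwise_identical(self):
        bounds = Bounds.cube(-2.0, 2.0, 4)
        pops = [
            initialize_population(
                bounds,
                OptimizerConfig(pop_size=6),
                np.random.default_rng(7),
                sphere,
            )
            for _ in range(2)
        ]
        assert np.array_equal(pops[0].positions, pops[1].positions)


class TestDynamicParams:
    @pytest.mark.parametrize(
        "t,T,expected_c", [(0, 10, 1.0), (10, 10, 0.0), (5, 10, 0.875)]
    )
    def test_decay_closed_form(self, t, T, expected_c, rng):
        params = compute_dynamic_params(t, T, 50, 5, rng)
        assert params.c == pytest.approx(expected_c, abs=0)

    def test_parameter_ranges(self, rng):
        for _ in range(20):
            p = compute_dynamic_params(3, 10, 40, 4, rng)
            assert 0.0 <= p.m <= 0.5 / 4
            assert 0.0 <= p.e <= 0.5 / 4
            assert 0.0 <= p.L <= 40 / 4

    def test_zero_total_iterations_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_dynamic_params(0, 0, 50, 5, rng)


class TestLevy:
    def test_sigma_matches_high_precision_evaluation(self):
        # independent oracle: arbitrary-precision evaluation via sympy
        import sympy as sp

        beta = sp.Rational(3, 2)
        expr = (
            sp.gamma(1 + beta)
            * sp.sin(sp.pi * beta / 2)
            / (sp.gamma((1 + beta) / 2) * sp.pi * 2 ** ((beta - 1) / 2))
        ) ** (1 / beta)
        oracle = float(expr.evalf(30))
        assert levy_sigma(1.5) == pytest.approx(oracle, abs=1e-10)
        assert levy_sigma(1.5) == pytest.approx(0.426, abs=5e-4)

    def test_mantegna_sigma_matches_high_precision_evaluation(self):
        import sympy as sp

        beta = sp.Rational(3, 2)
        expr = (
            sp.gamma(1 + beta)
            * sp.sin(sp.pi * beta / 2)
            / (sp.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
        ) ** (1 / beta)
        assert levy_sigma(1.5, mantegna=True) == pytest.approx(
            float(expr.evalf(30)), abs=1e-10
        )

    def test_zero_numerator_gives_zero_step(self, stub_rng_cls):
        rng = stub_rng_cls(uniforms=[0.0, 0.0], normals=[1.0, 1.0])
        assert np.all(levy_step(2, 1.5, rng) == 0.0)

    def test_invalid_beta_rejected(self, rng):
        with pytest.raises(ValueError):
            levy_step(2, 0.0, rng)
        with pytest.raises(ValueError):
            levy_sigma(-1.0)

    def test_seeded_reproducibility(self):
        a = levy_step(5, 1.5, np.random.default_rng(3))
        b = levy_step(5, 1.5, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestExploration:
    def test_mean_branch_hand_computed(self, stub_rng_cls):
        # N=4 -> stride s=1 -> every index takes the population-mean branch
        bounds = Bounds(np.array([-10.0, -10.0]), np.array([4.0, 8.0]))
        positions = [[0.0, 0.0], [1.0, 1.0], [2.0, 3.0], [1.0, 4.0]]
        pop = make_pop(positions, best=[0.0, 0.0], iteration=1)
        params = DynamicParams(m=0.0, L=0.0, e=0.0, c=0.875)
        u = [0.5, 0.75, 0.25, 0.5, 0.5, 0.5, 1.0, 0.0]
        rng = stub_rng_cls(uniforms=u)
        new = exploration_step(pop, bounds, params, rng)
        mean = np.array([1.0, 2.0])
        scale = 0.875 / math.pi
        expected = np.array(
            [
                mean + scale * np.array([2 * 0.5 - 1, 2 * 0.75 - 1]) * [4, 8],
                mean + scale * np.array([2 * 0.25 - 1, 2 * 0.5 - 1]) * [4, 8],
                mean + scale * np.array([2 * 0.5 - 1, 2 * 0.5 - 1]) * [4, 8],
                mean + scale * np.array([2 * 1.0 - 1, 2 * 0.0 - 1]) * [4, 8],
            ]
        )
        np.testing.assert_allclose(new, np.clip(expected, -10, [4, 8]))

    def test_final_iteration_freezes_otherwise_branch(self, rng):
        # c=0 -> W=0; with N=30 the stride is 3 and indices with
        # mod(i,3) not in {0,1} (1-based) keep their position exactly
        bounds = Bounds.cube(-5.0, 5.0, 3)
        positions = rng.uniform(-5, 5, size=(30, 3))
        pop = make_pop(positions, best=positions[0])
        params = DynamicParams(m=0.1, L=0.1, e=0.1, c=0.0)
        new = exploration_step(pop, bounds, params, rng)
        for i in range(30):
            branch = (i + 1) % 3
            if branch == 0:
                np.testing.assert_allclose(new[i], positions.mean(axis=0))
            elif branch == 1:
                np.testing.assert_allclose(new[i], pop.best_position)
            else:
                np.testing.assert_array_equal(new[i], positions[i])

    def test_population_at_best_with_zero_decay_is_invariant(self, rng):
        bounds = Bounds.cube(-5.0, 5.0, 2)
        best = np.array([1.5, -2.0])
        pop = make_pop(np.tile(best, (30, 1)), best=best)
        params = DynamicParams(m=0.1, L=0.1, e=0.1, c=0.0)
        new = exploration_step(pop, bounds, params, rng)
        np.testing.assert_allclose(new, pop.positions)


class TestRolling:
    def test_hand_computed_two_dimensional_case(self, stub_rng_cls):
        bounds = Bounds(np.array([-10.0, -10.0]), np.array([4.0, 8.0]))
        pop = make_pop([[0.0, 0.0]] * 4, best=[1.0, 2.0], iteration=1)
        params = DynamicParams(m=0.1, L=0.2, e=0.3, c=0.875)
        config = OptimizerConfig(max_iter=2)
        rng = stub_rng_cls(
            uniforms=[0.25, 0.5, 0.75, 0.5, 0.5], normals=[1.0, -2.0]
        )
        new = rolling_update(0, pop, bounds, params, config, rng)
        # independent arithmetic: r=0.25 -> sin(2*pi*r)=1 ->
        # A = UB - |UB*1/2| = [2, 4]; uniform draws map to [0, 2]
        roll = (0.1 * 0.3 + 0.2**2) * np.array([0.0, 2.0]) / 2
        sigma = (
            math.gamma(2.5)
            * math.sin(0.75 * math.pi)
            / (math.gamma(1.25) * math.pi * 2**0.25)
        ) ** (2.0 / 3.0)
        levy = 0.01 * 0.5 * sigma / np.abs(np.array([1.0, -2.0])) ** (2.0 / 3.0)
        expected = np.array([1.0, 2.0]) + roll + 0.875 * levy * [1.0, 2.0]
        np.testing.assert_allclose(new, expected, rtol=1e-12)

    def test_zero_biomechanics_reduces_to_levy_walk(self, stub_rng_cls):
        bounds = Bounds.cube(-10.0, 10.0, 2)
        pop = make_pop([[0.0, 0.0]] * 4, best=[1.0, 2.0], iteration=1)
        params = DynamicParams(m=0.0, L=0.0, e=0.0, c=0.5)
        config = OptimizerConfig(max_iter=2)
        rng = stub_rng_cls(
            uniforms=[0.3, 0.5, 0.5, 0.4, 0.4], normals=[1.0, 1.0]
        )
        new = rolling_update(0, pop, bounds, params, config, rng)
        sigma = levy_sigma(1.5)
        levy = 0.01 * 0.4 * sigma
        expected = np.array([1.0, 2.0]) * (1.0 + 0.5 * levy)
        np.testing.assert_allclose(new, expected, rtol=1e-12)

    def test_initial_iteration_amplitude_is_full_box(self, stub_rng_cls):
        # t=0 -> A = UB exactly, so the uniform draw spans (-UB, UB)
        bounds = Bounds(np.array([0.0, 0.0]), np.array([4.0, 8.0]))
        pop = make_pop([[0.0, 0.0]] * 4, best=[1.0, 1.0], iteration=0)
        params = DynamicParams(m=1.0, L=0.0, e=1.0, c=1.0)
        config = OptimizerConfig(max_iter=10)
        # uniform u = 0 and 1 hit the interval endpoints -A and +A
        rng = stub_rng_cls(uniforms=[0.9, 0.0, 1.0, 0.0, 0.0], normals=[1, 1])
        new = rolling_update(0, pop, bounds, params, config, rng)
        expected = np.array([1.0, 1.0]) + 1.0 * np.array([-4.0, 8.0]) / 2
        np.testing.assert_allclose(np.clip(expected, 0, [4, 8]), new)


class TestJumping:
    def test_hand_computed_two_dimensional_case(self, stub_rng_cls):
        bounds = Bounds(np.array([-10.0, -10.0]), np.array([4.0, 8.0]))
        pop = make_pop([[0.0, 0.0]] * 4, best=[1.0, 2.0], iteration=1)
        params = DynamicParams(m=0.1, L=0.2, e=0.3, c=0.875)
        config = OptimizerConfig(max_iter=2)
        rng = stub_rng_cls(
            uniforms=[0.25, 0.5, 0.5, 0.25, 0.5, 0.5], normals=[1.0, -2.0]
        )
        new = jumping_update(0, pop, bounds, params, config, rng)
        # independent arithmetic: r=0.25 -> cos(pi/2)=0 -> B=UB;
        # k=0.625, x=0.375, theta=pi/4, r'=1 -> alpha=exp(0.5)/pi
        alpha = math.exp(0.5) / math.pi
        u_b = np.array([4.0 * (2 * 0.5 - 1), 8.0 * (2 * 0.25 - 1)])
        jump = (
            (2 * 0.625 * 0.375**2 * math.sin(math.pi / 2))
            / (0.1 * 9.81)
            * (u_b / 2)
            * (1 - alpha)
        )
        sigma = levy_sigma(1.5)
        levy = 0.01 * 0.5 * sigma / np.abs(np.array([1.0, -2.0])) ** (2.0 / 3.0)
        expected = np.array([1.0, 2.0]) + jump + 0.875 * levy * [1.0, 2.0]
        np.testing.assert_allclose(new, expected, rtol=1e-12)

    def test_right_angle_launch_cancels_jump(self, stub_rng_cls):
        # r=0.5 -> theta=pi/2 -> sin(2 theta)=0 -> J=0
        bounds = Bounds.cube(-10.0, 10.0, 2)
        pop = make_pop([[0.0, 0.0]] * 4, best=[1.0, 2.0], iteration=1)
        params = DynamicParams(m=0.1, L=0.2, e=0.3, c=0.0)
        config = OptimizerConfig(max_iter=2)
        rng = stub_rng_cls(
            uniforms=[0.5, 0.5, 0.9, 0.1, 0.5, 0.5], normals=[1.0, 1.0]
        )
        new = jumping_update(0, pop, bounds, params, config, rng)
        np.testing.assert_allclose(new, [1.0, 2.0], atol=1e-15)

    def test_drag_coefficient_strictly_below_one(self):
        # alpha = exp(r'/T)/pi <= e/pi < 1 for any r' in [0, T]
        for frac in np.linspace(0.0, 1.0, 11):
            alpha = math.exp(frac) / math.pi
            assert alpha <= math.e / math.pi < 1.0


class TestGeneticOperators:
    def test_crossover_full_rate_returns_mutant(self, rng):
        # identical partner rows make the mutant row-independent of r1..r3
        base = np.array([2.0, -1.0, 0.5])
        positions = np.vstack([[9.0, 9.0, 9.0], np.tile(base, (4, 1))])
        pop = make_pop(positions, best=base)
        bounds = Bounds.cube(-10.0, 10.0, 3)
        trial = de_crossover(
            pop, 0, bounds, OptimizerConfig(crossover_rate=1.0), rng
        )
        np.testing.assert_allclose(trial, base)

    def test_crossover_zero_rate_keeps_target_except_jrand(self, rng):
        base = np.array([2.0, -1.0, 0.5])
        target = np.array([9.0, 9.0, 9.0])
        positions = np.vstack([target, np.tile(base, (4, 1))])
        pop = make_pop(positions, best=base)
        bounds = Bounds.cube(-10.0, 10.0, 3)
        trial = de_crossover(
            pop, 0, bounds, OptimizerConfig(crossover_rate=0.0), rng
        )
        differing = np.nonzero(trial != target)[0]
        assert differing.size == 1
        assert trial[differing[0]] == base[differing[0]]

    def test_zero_scale_factor_copies_a_partner(self, rng):
        positions = rng.uniform(-5, 5, size=(6, 2))
        pop = make_pop(positions, best=positions[0])
        bounds = Bounds.cube(-5.0, 5.0, 2)
        trial = de_crossover(
            pop,
            2,
            bounds,
            OptimizerConfig(crossover_rate=1.0, scale_factor=1e-300),
            rng,
        )
        # with F ~ 0 the mutant equals X_r1, one of the other rows
        assert any(
            np.allclose(trial, positions[j]) for j in range(6) if j != 2
        )

    def test_mutation_is_identity_at_final_iteration(self, rng):
        bounds = Bounds.cube(-1.0, 1.0, 5)
        x = rng.uniform(-1, 1, size=5)
        out = nonuniform_mutation(
            x, bounds, t=10, T=10, config=OptimizerConfig(mutation_prob=1.0), rng=rng
        )
        np.testing.assert_allclose(out, x)

    def test_mutation_endpoints_of_shrink_factor(self, stub_rng_cls):
        bounds = Bounds.cube(0.0, 1.0, 1)
        cfg = OptimizerConfig(mutation_prob=1.0)
        # mutate-draw 0 (< Pm), direction-draw 0 (up), r=1 -> Delta=0
        rng = stub_rng_cls(uniforms=[0.0, 0.0, 1.0])
        out = nonuniform_mutation(np.array([0.4]), bounds, 0, 10, cfg, rng)
        assert out[0] == pytest.approx(0.4)
        # r=0 -> Delta=y -> lands exactly on the upper bound
        rng = stub_rng_cls(uniforms=[0.0, 0.0, 0.0])
        out = nonuniform_mutation(np.array([0.4]), bounds, 0, 10, cfg, rng)
        assert out[0] == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
        t=st.integers(0, 10),
    )
    def test_mutation_never_leaves_bounds(self, x, seed, t):
        bounds = Bounds.cube(0.0, 1.0, 1)
        rng = np.random.default_rng(seed)
        out = nonuniform_mutation(
            np.array([x]),
            bounds,
            t,
            10,
            OptimizerConfig(mutation_prob=1.0),
            rng,
        )
        assert 0.0 <= out[0] <= 1.0

    @pytest.mark.parametrize(
        "current,trial,keep",
        [(0.7, 0.5, True), (0.5, 0.5, True), (0.1, 0.9, False)],
    )
    def test_greedy_selection_rule(self, current, trial, keep):
        assert greedy_select(current, trial) is keep

    def test_greedy_rejects_non_finite_trial(self):
        assert greedy_select(1.0, math.inf) is False
        assert greedy_select(1.0, math.nan) is False


class TestOptimize:
    def test_sphere_defaults_reach_tolerance(self):
        bounds = Bounds.cube(-5.0, 5.0, 5)
        finals = [
            optimize(sphere, bounds, OptimizerConfig(seed=s)).best_fitness
            for s in range(5)
        ]
        assert np.median(finals) < 1e-2

    def test_constant_objective_flat_history(self):
        bounds = Bounds.cube(-1.0, 1.0, 3)
        res = optimize(
            lambda x: 4.25, bounds, OptimizerConfig(pop_size=8, max_iter=20, seed=0)
        )
        assert res.best_fitness == 4.25
        assert np.all(res.history == 4.25)

    @pytest.mark.parametrize("ga", [True, False])
    def test_history_monotone_and_terminal(self, ga):
        def rosenbrock(x):
            return float(
                np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1 - x[:-1]) ** 2)
            )

        bounds = Bounds.cube(-2.0, 2.0, 4)
        res = optimize(
            rosenbrock,
            bounds,
            OptimizerConfig(pop_size=10, max_iter=30, seed=3, use_ga_operators=ga),
        )
        assert np.all(np.diff(res.history) <= 0)
        assert res.history[-1] == res.best_fitness
        assert np.all(res.best_position >= -2.0)
        assert np.all(res.best_position <= 2.0)

    def test_seeded_runs_bitwise_reproducible(self):
        bounds = Bounds.cube(-3.0, 3.0, 3)
        runs = [
            optimize(
                sphere, bounds, OptimizerConfig(pop_size=8, max_iter=15, seed=11)
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].best_position, runs[1].best_position)
        assert np.array_equal(runs[0].history, runs[1].history)
        assert runs[0].evaluations == runs[1].evaluations

    def test_non_finite_objective_treated_as_worst(self):
        def leaky(x):
            return math.nan if x[0] > 0 else float(np.sum(x**2))

        bounds = Bounds.cube(-1.0, 1.0, 2)
        res = optimize(
            leaky, bounds, OptimizerConfig(pop_size=8, max_iter=10, seed=2)
        )
        assert math.isfinite(res.best_fitness)

    def test_invalid_config_raises_before_evaluation(self):
        calls = []

        def spy(x):
            calls.append(1)
            return 0.0

        with pytest.raises(ValueError):
            optimize(spy, Bounds.cube(0, 1, 2), OptimizerConfig(pop_size=2))
        assert not calls

    def test_warm_start_points_enter_population(self):
        bounds = Bounds.cube(0.0, 1.0, 2)
        target = np.array([0.25, 0.75])

        def dist(x):
            return float(np.sum((x - target) ** 2))

        res = optimize(
            dist,
            bounds,
            OptimizerConfig(pop_size=6, max_iter=1, seed=0),
            initial_points=target[None, :],
        )
        assert res.best_fitness == 0.0
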
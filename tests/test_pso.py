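"""Unit and property tests for the shrinkage-factor particle swarm."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmseg import pso
from conftest import quadratic


def make_config(**kwargs) -> pso.PSOConfig:
    return pso.PSOConfig(**kwargs)


class TestShrinkageFactor:
    @pytest.mark.parametrize(
        "n, expected",
        [(0, 0.9), (100, 0.4), (50, 0.65), (25, 0.775), (75, 0.525)],
    )
    def test_linear_schedule(self, n, expected):
        config = make_config(p_max=0.9, p_min=0.4, n_max=100)
        assert pso.shrinkage_factor(n, config) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("n", [-1, 101])
    def test_out_of_range_iteration_rejected(self, n):
        with pytest.raises(ValueError):
            pso.shrinkage_factor(n, make_config(n_max=100))

    @given(
        n1=st.integers(min_value=0, max_value=100),
        n2=st.integers(min_value=0, max_value=100),
    )
    @settings(deadline=None)
    def test_affine_in_iteration(self, n1, n2):
        """factor(n1) + factor(n2) == 2 * factor(midpoint) for even sums."""
        if (n1 + n2) % 2:
            n2 += 1 if n2 < 100 else -1
        config = make_config(p_max=0.9, p_min=0.4, n_max=100)
        lhs = pso.shrinkage_factor(n1, config) + pso.shrinkage_factor(n2, config)
        rhs = 2.0 * pso.shrinkage_factor((n1 + n2) // 2, config)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_bounded_by_schedule_endpoints(self):
        config = make_config(p_max=0.9, p_min=0.4, n_max=17)
        factors = [pso.shrinkage_factor(n, config) for n in range(18)]
        assert all(0.4 <= f <= 0.9 for f in factors)
        assert factors == sorted(factors, reverse=True)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"swarm_size": 1},
            {"n_max": 0},
            {"p_max": 0.3, "p_min": 0.4},
            {"p_min": 0.0, "p_max": 0.0},
            {"c1": 0.0, "c2": 0.0},
            {"v_max": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_config(**kwargs)

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError):
            pso.SearchBounds([5.0], [5.0])


class TestInitializeSwarm:
    def test_positions_within_bounds(self, unit_bounds):
        config = make_config(swarm_size=5, seed=3)
        state = pso.initialize_swarm(config, unit_bounds, quadratic)
        assert len(state.particles) == 5
        for p in state.particles:
            assert unit_bounds.contains(p.position)

    def test_seeded_determinism(self, unit_bounds):
        config = make_config(swarm_size=5, seed=11)
        s1 = pso.initialize_swarm(config, unit_bounds, quadratic)
        s2 = pso.initialize_swarm(config, unit_bounds, quadratic)
        for p1, p2 in zip(s1.particles, s2.particles):
            np.testing.assert_array_equal(p1.position, p2.position)
            np.testing.assert_array_equal(p1.velocity, p2.velocity)
        assert s1.gbest_fitness == s2.gbest_fitness

    def test_constant_objective_gbest(self, unit_bounds):
        state = pso.initialize_swarm(make_config(seed=1), unit_bounds, lambda x: 3.0)
        assert state.gbest_fitness == 3.0

    def test_gbest_is_max_of_pbests(self, unit_bounds):
        state = pso.initialize_swarm(make_config(seed=2), unit_bounds, quadratic)
        assert state.gbest_fitness == max(p.pbest_fitness for p in state.particles)

    def test_nan_objective_raises(self, unit_bounds):
        with pytest.raises(pso.EvaluationError):
            pso.initialize_swarm(make_config(seed=1), unit_bounds, lambda x: float("nan"))


class TestVelocityUpdate:
    def test_pure_inertia_is_identity(self):
        particle = pso.Particle(
            position=np.array([1.0]), velocity=np.array([2.0]),
            pbest_position=np.array([1.0]), pbest_fitness=0.0,
        )
        config = make_config(c1=1e-9, c2=1e-9, inertia_weight=1.0, v_max=10.0)
        v = pso.velocity_update(
            particle, np.array([1.0]), 1.0, config, (np.zeros(1), np.zeros(1))
        )
        np.testing.assert_allclose(v, [2.0])

    def test_equilibrium_stays_at_rest(self):
        x = np.array([5.0])
        particle = pso.Particle(position=x, velocity=np.zeros(1),
                                pbest_position=x.copy(), pbest_fitness=0.0)
        v = pso.velocity_update(particle, x.copy(), 0.7, make_config(v_max=10.0),
                                (np.ones(1), np.ones(1)))
        np.testing.assert_array_equal(v, [0.0])

    def test_hand_computed_update(self):
        # 0.5 * (1*2 + 2*1*3 + 0) = 4.0, within the clamp
        particle = pso.Particle(position=np.array([0.0]), velocity=np.array([2.0]),
                                pbest_position=np.array([3.0]), pbest_fitness=0.0)
        config = make_config(c1=2.0, c2=1e-9, inertia_weight=1.0, v_max=10.0)
        v = pso.velocity_update(particle, np.array([0.0]), 0.5, config,
                                (np.ones(1), np.zeros(1)))
        np.testing.assert_allclose(v, [4.0], atol=1e-8)

    def test_clamped_to_v_max(self):
        particle = pso.Particle(position=np.array([0.0]), velocity=np.array([50.0]),
                                pbest_position=np.array([0.0]), pbest_fitness=0.0)
        config = make_config(inertia_weight=1.0, v_max=10.0)
        v = pso.velocity_update(particle, np.array([0.0]), 1.0, config,
                                (np.zeros(1), np.zeros(1)))
        np.testing.assert_array_equal(v, [10.0])

    def test_dimension_mismatch_rejected(self):
        particle = pso.Particle(position=np.zeros(2), velocity=np.zeros(2),
                                pbest_position=np.zeros(2), pbest_fitness=0.0)
        with pytest.raises(ValueError, match="dimension mismatch"):
            pso.velocity_update(particle, np.zeros(3), 1.0, make_config(v_max=1.0),
                                (np.zeros(2), np.zeros(2)))


class TestPositionUpdate:
    @pytest.mark.parametrize(
        "position, velocity, expected_pos, expected_vel",
        [([10.0], [5.0], [15.0], [5.0]),
         ([250.0], [10.0], [255.0], [0.0]),
         ([0.0], [-1.0], [0.0], [0.0])],
    )
    def test_move_and_clamp(self, unit_bounds, position, velocity, expected_pos, expected_vel):
        particle = pso.Particle(position=np.array(position), velocity=np.zeros(1),
                                pbest_position=np.array(position), pbest_fitness=0.0)
        new_pos, new_vel = pso.position_update(particle, np.array(velocity), unit_bounds)
        np.testing.assert_array_equal(new_pos, expected_pos)
        np.testing.assert_array_equal(new_vel, expected_vel)


class TestSwarmStep:
    def test_gbest_never_decreases(self, unit_bounds):
        config = make_config(swarm_size=10, seed=4)
        state = pso.initialize_swarm(config, unit_bounds, quadratic)
        previous = state.gbest_fitness
        for _ in range(50):
            pso.swarm_step(state, config, unit_bounds, quadratic)
            assert state.gbest_fitness >= previous
            previous = state.gbest_fitness

    def test_fixed_point_at_optimum(self, unit_bounds):
        config = make_config(swarm_size=2, seed=0, v_max=10.0)
        state = pso.initialize_swarm(config, unit_bounds, quadratic)
        for p in state.particles:
            p.position = np.array([128.0])
            p.velocity = np.zeros(1)
            p.pbest_position = np.array([128.0])
            p.pbest_fitness = 0.0
        state.gbest_position = np.array([128.0])
        state.gbest_fitness = 0.0
        pso.swarm_step(state, config, unit_bounds, quadratic)
        for p in state.particles:
            np.testing.assert_array_equal(p.position, [128.0])
            np.testing.assert_array_equal(p.velocity, [0.0])
        assert state.iteration == 1

    def test_converges_to_quadratic_maximizer(self, unit_bounds):
        config = make_config(swarm_size=20, n_max=100, seed=8)
        state = pso.initialize_swarm(config, unit_bounds, quadratic)
        for _ in range(100):
            pso.swarm_step(state, config, unit_bounds, quadratic)
        assert abs(state.gbest_position[0] - 128.0) <= 0.5

    def test_positions_stay_in_bounds_over_many_random_steps(self):
        """Containment audited across 1000 recorded swarm steps."""
        bounds = pso.SearchBounds([-3.0, 0.0], [2.0, 255.0])
        rng = np.random.default_rng(17)

        def noisy_objective(x):
            return float(-np.sum(x**2) + rng.normal())

        checked = 0
        for seed in range(10):
            config = make_config(swarm_size=8, n_max=100, seed=seed)
            state = pso.initialize_swarm(config, bounds, noisy_objective)
            for _ in range(100):
                pso.swarm_step(state, config, bounds, noisy_objective)
                for p in state.particles:
                    assert bounds.contains(p.position)
                checked += 1
        assert checked == 1000


class TestOptimize:
    def test_reaches_quadratic_optimum(self, unit_bounds):
        result = pso.optimize(quadratic, unit_bounds, make_config(seed=1))
        assert result.best_fitness == pytest.approx(0.0, abs=0.25)

    def test_standard_pso_reaches_quadratic_optimum(self, unit_bounds):
        result = pso.optimize_standard(quadratic, unit_bounds, make_config(seed=1))
        assert result.best_fitness == pytest.approx(0.0, abs=0.25)

    @pytest.mark.parametrize("runner", [pso.optimize, pso.optimize_standard])
    def test_trace_monotone_and_sized(self, unit_bounds, runner):
        result = runner(quadratic, unit_bounds, make_config(seed=5, n_max=40))
        assert result.iterations_run == len(result.fitness_trace) == 40
        assert np.all(np.diff(result.fitness_trace) >= 0)

    def test_seeded_determinism_bitwise(self, unit_bounds):
        config = make_config(seed=9)
        r1 = pso.optimize(quadratic, unit_bounds, config)
        r2 = pso.optimize(quadratic, unit_bounds, config)
        np.testing.assert_array_equal(r1.fitness_trace, r2.fitness_trace)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        assert r1.best_fitness == r2.best_fitness

    def test_stall_detection_stops_early(self, unit_bounds):
        config = make_config(seed=2, n_max=100, stall_window=5, stall_tolerance=1e-12)
        result = pso.optimize(lambda x: 1.0, unit_bounds, config)
        assert result.converged_early
        assert result.iterations_run < 100

    def test_quadratic_success_rate(self, unit_bounds):
        """|best - argmax| <= 0.5 in at least 99 of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            config = make_config(swarm_size=20, n_max=100, seed=seed)
            result = pso.optimize(quadratic, unit_bounds, config)
            hits += abs(result.best_position[0] - 128.0) <= 0.5
        assert hits >= 99

    def test_comparison_harness_equal_trace_lengths(self, unit_bounds):
        results = pso.compare_optimizers(quadratic, unit_bounds, make_config(seed=3, n_max=30))
        assert results["improved"].iterations_run == results["standard"].iterations_run == 30

    def test_negative_infinity_is_tolerated_as_infeasible(self, unit_bounds):
        """-inf marks infeasible candidates; the swarm still finds feasible ones."""

        def gappy(x):
            return quadratic(x) if x[0] >= 100.0 else float("-inf")

        result = pso.optimize(gappy, unit_bounds, make_config(seed=6))
        assert np.isfinite(result.best_fitness)
        assert result.best_position[0] >= 100.0
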
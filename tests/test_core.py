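import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redpiranha.core import (
    Agent,
    ConfigurationError,
    ObjectiveEvaluationError,
    ObjectiveSpec,
    RPOConfig,
    Sense,
    attack_coefficient_schedule,
    attacking_update,
    cartesian_distance,
    checkpoint_iterations,
    compute_prey_position,
    detect_and_resolve_collisions,
    encircling_update,
    greedy_select_phase_best,
    partition_iterations,
    run_rpo,
    sample_search_coefficients,
    scout_count,
    searching_update,
    select_scouts,
    spiral_parameter,
)
from redpiranha.rng import RandomStream, ScriptedStream

TOL = 5e-3


class TestPartitionIterations:
    @pytest.mark.parametrize(
        "z,expected",
        [(10, (3, 3, 4)), (3, (1, 1, 1)), (11, (3, 3, 5)), (12, (4, 4, 4))],
    )
    def test_examples(self, z, expected):
        schedule = partition_iterations(z)
        assert (schedule.z_srch, schedule.z_enc, schedule.z_att) == expected

    @pytest.mark.parametrize("z", [0, 1, 2, -5])
    def test_too_few_iterations(self, z):
        with pytest.raises(ConfigurationError):
            partition_iterations(z)

    @given(st.integers(min_value=3, max_value=10_000))
    def test_conservation_and_uniformity(self, z):
        schedule = partition_iterations(z)
        assert schedule.z_srch + schedule.z_enc + schedule.z_att == z
        assert schedule.z_srch == schedule.z_enc == z // 3
        assert schedule.z_att >= schedule.z_srch


class TestScouts:
    def test_scout_count_worked_example(self):
        assert scout_count(10, 4) == 3

    def test_scout_count_whole_swarm_scaling(self):
        assert scout_count(10, 10) == 1

    def test_scout_count_bad_scaling(self):
        with pytest.raises(ConfigurationError):
            scout_count(10, 1.5)
        with pytest.raises(ConfigurationError):
            scout_count(10, 11)

    def test_three_clusters(self, rng):
        scouts, clusters = select_scouts(10, 3, rng)
        assert len(scouts) == 3
        assert len(clusters) == 7
        assert set(clusters.values()) <= {0, 1, 2}
        assert set(scouts).isdisjoint(clusters)

    def test_single_cluster(self, rng):
        scouts, clusters = select_scouts(10, 1, rng)
        assert len(scouts) == 1
        assert set(clusters.values()) == {0}
        assert len(clusters) == 9

    def test_cluster_sizes_follow_ceiling_rule(self, rng):
        # n=7, lam=4: ceil(3/4)=1 member per cluster, last cluster empty
        scouts, clusters = select_scouts(7, 4, rng)
        sizes = [list(clusters.values()).count(c) for c in range(4)]
        assert sizes == [1, 1, 1, 0]

    @given(
        st.integers(min_value=1, max_value=60),
        st.integers(min_value=1, max_value=60),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_partition_is_exhaustive(self, n, lam, seed):
        if lam > n:
            with pytest.raises(ConfigurationError):
                select_scouts(n, lam, RandomStream(seed))
            return
        scouts, clusters = select_scouts(n, lam, RandomStream(seed))
        assert sorted(scouts + list(clusters)) == list(range(n))
        cap = math.ceil((n - lam) / lam) if n > lam else 0
        sizes = [list(clusters.values()).count(c) for c in range(lam)]
        assert all(s <= cap for s in sizes)
        # all clusters before the last non-empty one are full
        assert sizes == sorted(sizes, reverse=True)


class TestSearchCoefficients:
    def test_lower_extreme(self):
        # r1=1, r2=0 fixes A = -2 regardless of r3; r4 gives C
        a, c = sample_search_coefficients(ScriptedStream([1, 0.0, 0.5, 0.25]))
        assert a == -2.0
        assert c == 0.5

    def test_upper_extreme(self):
        a, _ = sample_search_coefficients(ScriptedStream([0, 0.3, 1.0, 0.0]))
        assert a == 2.0

    def test_empirical_support(self, rng):
        draws = np.array(
            [sample_search_coefficients(rng) for _ in range(100_000)]
        )
        a, c = draws[:, 0], draws[:, 1]
        assert np.all((a >= -2) & (a <= 2))
        # the forbidden contraction band is never hit
        assert not np.any((a >= -1) & (a <= 1))
        negative = a < 0
        assert np.all(a[negative] < -1)
        assert np.all(a[~negative] > 1)
        # both branches are exercised roughly evenly
        assert 0.45 < negative.mean() < 0.55
        assert np.all((c >= 0) & (c <= 2))


class TestSearchingUpdate:
    def test_worked_example_cell(self, quadratic_spec):
        agent = Agent(position=np.array([-0.451, 1.913]), fitness=14.476)
        searching_update(
            agent, np.array([1.983, 0.562]), a=-1.8945, c=0.568,
            spec=quadratic_spec,
        )
        np.testing.assert_allclose(agent.position, [4.972, 3.582], atol=TOL)
        assert agent.fitness == quadratic_spec.evaluate(agent.position)
        # the printed objective value belongs to the printed (rounded) position
        assert quadratic_spec.evaluate(np.array([4.972, 3.582])) == pytest.approx(
            47.014, abs=TOL)
        assert len(agent.history) == 1

    def test_zero_distance_fixed_point(self, quadratic_spec):
        scout = np.array([2.0, 1.0])
        # position chosen as C * scout so that D = 0
        agent = Agent(position=0.5 * scout, fitness=0.0)
        searching_update(agent, scout, a=1.7, c=0.5, spec=quadratic_spec)
        np.testing.assert_array_equal(agent.position, scout)

    def test_out_of_range_component_clamped(self, quadratic_spec):
        # this cell computes x2 = -7.106 before clamping
        agent = Agent(position=np.array([3.114, -3.367]), fitness=27.279)
        searching_update(
            agent, np.array([1.983, 0.562]), a=1.987, c=0.876,
            spec=quadratic_spec,
        )
        assert agent.position[1] == -5.0
        np.testing.assert_allclose(agent.position, [-0.753, -5.0], atol=TOL)

    def test_non_finite_objective_is_reported(self):
        spec = ObjectiveSpec(1, [-1.0], [1.0], lambda x: float("nan"))
        agent = Agent(position=np.array([0.0]), fitness=0.0)
        with pytest.raises(ObjectiveEvaluationError, match="agent 3"):
            searching_update(agent, np.array([0.5]), 1.5, 1.0, spec,
                             context="searching iteration 1, agent 3")


class TestGreedySelection:
    def test_single_entry_identity(self):
        agent = Agent(position=np.array([1.0]), fitness=5.0)
        agent.record()
        greedy_select_phase_best(agent, Sense.MINIMIZE)
        assert agent.fitness == 5.0
        assert agent.history == []

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            greedy_select_phase_best(
                Agent(position=np.array([1.0]), fitness=5.0), Sense.MINIMIZE
            )

    @pytest.mark.parametrize("sense", [Sense.MINIMIZE, Sense.MAXIMIZE])
    def test_matches_exhaustive_scan(self, sense, rng):
        for _ in range(200):
            length = rng.integers(1, 11)
            entries = [
                (rng.uniform_box(np.array([-9.0, -9.0]), np.array([9.0, 9.0])),
                 rng.uniform() * 20 - 10)
                for _ in range(length)
            ]
            agent = Agent(position=entries[0][0], fitness=entries[0][1])
            agent.history = [(p.copy(), f) for p, f in entries]
            greedy_select_phase_best(agent, sense)
            # independent oracle: explicit linear scan
            best = entries[0]
            for entry in entries[1:]:
                if (entry[1] < best[1]) if sense is Sense.MINIMIZE else (entry[1] > best[1]):
                    best = entry
            assert agent.fitness == best[1]
            np.testing.assert_array_equal(agent.position, best[0])


class TestPreyPosition:
    def test_encircling_worked_example(self):
        positions = [np.array(p) for p in
                     [(-3.308, -3.625), (-0.3487, -2.967), (-1.521, -5.000)]]
        prey = compute_prey_position(positions, [-6.024, -1.675, -0.334], 3,
                                     Sense.MINIMIZE)
        np.testing.assert_allclose(prey, [-1.726, -3.864], atol=TOL)

    def test_attacking_worked_example(self):
        positions = [np.array(p) for p in
                     [(-1.493, -2.573), (-0.749, -2.441), (-0.667, -2.511)]]
        prey = compute_prey_position(positions, [-5.270, -3.570, -3.302], 3,
                                     Sense.MINIMIZE)
        np.testing.assert_allclose(prey, [-0.970, -2.508], atol=TOL)

    def test_k_one_is_best_agent(self):
        positions = [np.array([1.0, 1.0]), np.array([2.0, 2.0])]
        prey = compute_prey_position(positions, [3.0, 1.0], 1, Sense.MINIMIZE)
        np.testing.assert_array_equal(prey, positions[1])

    def test_ties_take_lower_index(self):
        positions = [np.array([0.0]), np.array([10.0]), np.array([20.0])]
        prey = compute_prey_position(positions, [1.0, 1.0, 1.0], 2, Sense.MINIMIZE)
        np.testing.assert_array_equal(prey, [5.0])

    def test_invalid_k(self):
        with pytest.raises(ConfigurationError):
            compute_prey_position([np.zeros(2)], [0.0], 2, Sense.MINIMIZE)


class TestEncircling:
    def test_distance_vector_worked_example(self, quadratic_spec):
        agent = Agent(position=np.array([1.977, -1.052]), fitness=9.841)
        prey = np.array([-1.726, -3.864])
        d = np.abs(prey - agent.position)
        np.testing.assert_allclose(d, [3.703, 2.812], atol=TOL)

    def test_spiral_parameter_schedule(self):
        assert spiral_parameter(1, 3) == pytest.approx(0.3333, abs=1e-4)
        assert spiral_parameter(2, 3) == pytest.approx(-0.3333, abs=1e-4)
        assert spiral_parameter(3, 3) == -1.0

    @given(st.integers(min_value=1, max_value=500))
    def test_spiral_parameter_strictly_decreasing(self, z_enc):
        values = [spiral_parameter(t, z_enc) for t in range(1, z_enc + 1)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] == -1.0

    def test_final_iteration_closed_form(self, quadratic_spec):
        # at l = -1, cos(-2*pi) = 1 so the move is D * e^-b + prey
        agent = Agent(position=np.array([1.0, 2.0]), fitness=0.0)
        prey = np.array([-1.0, -2.0])
        expected = np.abs(prey - agent.position) * math.exp(-1.0) + prey
        encircling_update(agent, prey, t=3, z_enc=3, b=1.0, spec=quadratic_spec)
        np.testing.assert_allclose(agent.position, expected, atol=1e-12)


class TestAttacking:
    def test_coefficient_schedule(self):
        assert attack_coefficient_schedule(4, 4) == 0.0
        assert attack_coefficient_schedule(1, 4) == 1.5
        assert attack_coefficient_schedule(1, 2) == 1.0
        values = [attack_coefficient_schedule(t, 7) for t in range(1, 8)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_worked_example_cell(self, quadratic_spec):
        agent = Agent(position=np.array([-0.619, -2.527]), fitness=-3.142)
        attacking_update(agent, np.array([-0.970, -2.508]), a=0.237, c=1.689,
                         spec=quadratic_spec, sense=Sense.MINIMIZE)
        np.testing.assert_allclose(agent.position, [-1.211, -2.914], atol=TOL)
        assert agent.fitness == pytest.approx(-4.650, abs=TOL)

    def test_zero_coefficient_lands_on_prey(self, quadratic_spec):
        agent = Agent(position=np.array([4.0, 4.0]), fitness=59.0)
        prey = np.array([-2.0, -3.0])
        attacking_update(agent, prey, a=0.0, c=1.3, spec=quadratic_spec,
                         sense=Sense.MINIMIZE)
        np.testing.assert_array_equal(agent.position, prey)

    def test_worse_candidate_is_rejected(self, quadratic_spec):
        position = np.array([-2.667, -3.333])  # essentially optimal
        fitness = quadratic_spec.evaluate(position)
        agent = Agent(position=position.copy(), fitness=fitness)
        attacking_update(agent, np.array([4.0, 4.0]), a=0.9, c=1.7,
                         spec=quadratic_spec, sense=Sense.MINIMIZE)
        np.testing.assert_array_equal(agent.position, position)
        assert agent.fitness == fitness


class TestCartesianDistance:
    def test_three_four_five(self):
        assert cartesian_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0

    def test_identity(self):
        x = np.array([1.0, -2.0, 3.0])
        assert cartesian_distance(x, x) == 0.0

    def test_matches_termwise_oracle(self, rng):
        x = rng.uniform_box(np.full(7, -10.0), np.full(7, 10.0))
        y = rng.uniform_box(np.full(7, -10.0), np.full(7, 10.0))
        oracle = math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
        assert cartesian_distance(x, y) == pytest.approx(oracle, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cartesian_distance(np.zeros(2), np.zeros(3))

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=8),
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=8),
    )
    def test_symmetry(self, xs, ys):
        size = min(len(xs), len(ys))
        x, y = np.array(xs[:size]), np.array(ys[:size])
        assert cartesian_distance(x, y) == cartesian_distance(y, x)


class TestCheckpoints:
    def test_worked_example(self):
        assert checkpoint_iterations(7, 3) == {1, 3, 5}

    def test_disabled(self):
        assert checkpoint_iterations(7, 0) == set()

    def test_single_checkpoint(self):
        assert checkpoint_iterations(7, 1) == {6}

    def test_out_of_range_indices_dropped(self):
        # stride 0 would give negative indices; all dropped
        assert checkpoint_iterations(2, 5) == set()

    @given(st.integers(0, 200), st.integers(0, 50))
    def test_always_within_phase(self, z_att, n_ck):
        points = checkpoint_iterations(z_att, n_ck)
        assert all(1 <= p <= z_att for p in points)
        assert len(points) <= n_ck


class TestCollisions:
    def _spec(self):
        return ObjectiveSpec(2, [-5.0, -5.0], [5.0, 5.0],
                             lambda x: float(np.sum(x**2)))

    def test_weaker_agent_relocates(self, rng):
        spec = self._spec()
        strong = Agent(position=np.array([0.1, 0.0]), fitness=0.01)
        weak = Agent(position=np.array([1.0, 0.0]), fitness=1.0)
        detect_and_resolve_collisions([strong, weak], delta=0.5, rng=rng,
                                      spec=spec, sense=Sense.MINIMIZE)
        np.testing.assert_array_equal(strong.position, [0.1, 0.0])
        assert not np.array_equal(weak.position, [1.0, 0.0])
        assert weak.fitness == spec.evaluate(weak.position)

    def test_boundary_distance_is_not_a_collision(self, rng):
        spec = self._spec()
        a = Agent(position=np.array([0.0, 0.0]), fitness=0.0)
        b = Agent(position=np.array([1.0, 0.0]), fitness=1.0)
        detect_and_resolve_collisions([a, b], delta=0.5, rng=rng, spec=spec,
                                      sense=Sense.MINIMIZE)
        np.testing.assert_array_equal(b.position, [1.0, 0.0])

    def test_tie_keeps_lower_index(self, rng):
        spec = self._spec()
        a = Agent(position=np.array([0.0, 0.0]), fitness=7.0)
        b = Agent(position=np.array([0.1, 0.0]), fitness=7.0)
        detect_and_resolve_collisions([a, b], delta=1.0, rng=rng, spec=spec,
                                      sense=Sense.MINIMIZE)
        np.testing.assert_array_equal(a.position, [0.0, 0.0])
        assert not np.array_equal(b.position, [0.1, 0.0])

    def test_zero_shield_is_pass_through(self, rng):
        spec = self._spec()
        a = Agent(position=np.array([0.0, 0.0]), fitness=0.0)
        b = Agent(position=np.array([0.0, 0.0]), fitness=1.0)
        detect_and_resolve_collisions([a, b], delta=0.0, rng=rng, spec=spec,
                                      sense=Sense.MINIMIZE)
        np.testing.assert_array_equal(b.position, [0.0, 0.0])

    def test_single_sweep_uses_pre_resolution_positions(self, rng):
        spec = self._spec()
        # chain: a-b collide and b-c collide; c must be judged against
        # b's original position even though b relocates
        a = Agent(position=np.array([0.0, 0.0]), fitness=0.0)
        b = Agent(position=np.array([0.5, 0.0]), fitness=0.25)
        c = Agent(position=np.array([1.0, 0.0]), fitness=1.0)
        detect_and_resolve_collisions([a, b, c], delta=0.3, rng=rng, spec=spec,
                                      sense=Sense.MINIMIZE)
        np.testing.assert_array_equal(a.position, [0.0, 0.0])
        assert not np.array_equal(b.position, [0.5, 0.0])
        assert not np.array_equal(c.position, [1.0, 0.0])


class TestRunRPO:
    def test_never_worse_than_best_initial(self, quadratic_spec):
        for seed in range(5):
            config = RPOConfig(n=8, z=9, seed=seed)
            result = run_rpo(quadratic_spec, config)
            rng = RandomStream(seed)
            initial_best = min(
                quadratic_spec.evaluate(
                    rng.uniform_box(quadratic_spec.lower, quadratic_spec.upper))
                for _ in range(8)
            )
            assert result.best_fitness <= initial_best

    def test_positions_stay_in_bounds(self, quadratic_spec):
        config = RPOConfig(n=10, z=15, seed=2, delta=0.4, n_ck=2,
                           collision_enabled=True)
        result = run_rpo(quadratic_spec, config)
        for record in result.trace:
            assert np.all(record.positions >= quadratic_spec.lower)
            assert np.all(record.positions <= quadratic_spec.upper)

    def test_best_fitness_is_trace_optimum(self, quadratic_spec):
        result = run_rpo(quadratic_spec, RPOConfig(n=10, z=12, seed=4))
        trace_min = min(float(r.fitnesses.min()) for r in result.trace)
        assert result.best_fitness == trace_min

    def test_fixed_seed_traces_are_bit_identical(self, quadratic_spec):
        config = RPOConfig(n=10, z=12, seed=11)
        r1 = run_rpo(quadratic_spec, config)
        r2 = run_rpo(quadratic_spec, config)
        assert r1.best_fitness == r2.best_fitness
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        assert len(r1.trace) == len(r2.trace)
        for a, b in zip(r1.trace, r2.trace):
            np.testing.assert_array_equal(a.positions, b.positions)
            np.testing.assert_array_equal(a.fitnesses, b.fitnesses)

    def test_sphere_convergence(self, sphere_spec):
        # threshold frozen from 20 reference runs (median 1.4e-10,
        # worst 4.9e-6); 1e-3 leaves three orders of magnitude of slack
        finals = [
            run_rpo(sphere_spec, RPOConfig(n=20, z=60, seed=seed)).best_fitness
            for seed in range(20)
        ]
        assert np.median(finals) < 1e-3

    def test_maximize_sense(self):
        spec = ObjectiveSpec(2, [-5.0, -5.0], [5.0, 5.0],
                             lambda x: -float(np.sum(x**2)),
                             sense=Sense.MAXIMIZE)
        result = run_rpo(spec, RPOConfig(n=10, z=30, seed=0))
        assert result.best_fitness > -1e-3

    def test_early_stop_on_plateau(self):
        spec = ObjectiveSpec(1, [-1.0], [1.0], lambda x: 1.0)
        config = RPOConfig(n=5, z=30, seed=0, xi=2, early_stop_enabled=True)
        result = run_rpo(spec, config)
        assert result.realized_iterations == 1

    def test_attacking_phase_monotone_per_agent(self, quadratic_spec):
        result = run_rpo(quadratic_spec, RPOConfig(n=10, z=30, seed=5))
        attacking = [r for r in result.trace if r.phase == "attacking"]
        fits = np.stack([r.fitnesses for r in attacking])
        assert np.all(np.diff(fits, axis=0) <= 1e-12)

    def test_invalid_configs(self):
        with pytest.raises(ConfigurationError):
            RPOConfig(n=10, z=30, xi=1.0)
        with pytest.raises(ConfigurationError):
            RPOConfig(n=10, z=30, k=11)
        with pytest.raises(ConfigurationError):
            RPOConfig(n=10, z=30, lam=11)
        with pytest.raises(ConfigurationError):
            RPOConfig(n=10, z=30, delta=-0.1)
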
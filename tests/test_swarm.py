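"""Swarm engine: update rules, recruitment, boundaries, reproducibility."""

import numpy as np
import pytest

from myoswarm import (
    CurveSpec,
    EnergyParams,
    SwarmParams,
    SwarmSimulation,
    build_curve,
    inertia,
    run_simulation,
    velocity_step,
)

ENERGY = EnergyParams(ideal_distance=1.1, search_distance=0.5)


def make_sim(curve, swarm_params=None, energy=ENERGY, seed=0):
    swarm_params = swarm_params or SwarmParams(swarm_size=8, t_max=20)
    sim = SwarmSimulation(curve, energy, swarm_params, rng=np.random.default_rng(seed))
    sim.initialize()
    return sim


class TestInertia:
    def test_endpoints_and_midpoint(self):
        p = SwarmParams(omega_min=0.4, omega_max=0.9, t_max=200)
        assert inertia(0, p) == pytest.approx(0.9)
        assert inertia(200, p) == pytest.approx(0.4)
        assert inertia(100, p) == pytest.approx(0.65)

    def test_out_of_range_iteration_rejected(self):
        with pytest.raises(ValueError):
            inertia(-1, SwarmParams())


class TestVelocityStep:
    def test_direct_arithmetic(self):
        v = velocity_step(
            v=np.array(0.0), r=np.array(0.0), p=np.array(1.0), g=np.array(2.0),
            omega=0.7, c1=2.0, c2=2.0, r1=np.array(0.5), r2=np.array(0.5),
        )
        assert v == pytest.approx(3.0)

    def test_zero_coefficients_keep_velocity(self):
        v = velocity_step(
            v=np.array([1.5, -0.3]), r=np.array([5.0, 6.0]),
            p=np.array([4.0, 7.0]), g=np.array([3.0, 8.0]),
            omega=1.0, c1=0.0, c2=0.0, r1=np.array([0.2, 0.8]), r2=np.array([0.9, 0.1]),
        )
        assert np.allclose(v, [1.5, -0.3])

    def test_converged_fixed_point(self):
        r = np.array([2.0, 3.0])
        v = velocity_step(np.zeros(2), r, r, r, 0.9, 2.0, 2.0,
                          np.array([0.3, 0.7]), np.array([0.6, 0.1]))
        assert np.allclose(v, 0.0)


class TestInitialization:
    def test_each_member_has_one_interior_cluster(self, straight40):
        sim = make_sim(straight40, SwarmParams(swarm_size=60, t_max=10))
        assert sim.x.shape == (60, 1)
        assert np.all((sim.x >= 0) & (sim.x <= 40))

    def test_velocities_zero_and_personal_bests_equal_positions(self, straight40):
        sim = make_sim(straight40)
        assert np.all(sim.v == 0)
        assert np.array_equal(sim.pbest, sim.x)

    def test_global_best_is_the_minimum_energy_member(self, straight40):
        sim = make_sim(straight40)
        energies = sim._energies(sim.x)
        assert sim.f_g == pytest.approx(energies.min())
        assert np.allclose(sim.gbest, sim.x[np.argmin(energies)])


class TestPositionUpdate:
    def test_plain_advection(self, straight40):
        sim = make_sim(straight40)
        sim.x = np.full((8, 1), 5.0)
        sim.v = np.full((8, 1), 0.4)
        sim.update_position()
        assert np.allclose(sim.x, 5.4)

    def test_absorbing_boundary_resets_position_and_velocity(self, straight40):
        sim = make_sim(straight40)
        sim.x = np.full((8, 1), 39.9)
        sim.v = np.full((8, 1), 1.0)
        sim.update_position()
        assert np.allclose(sim.x, 40.0)
        assert np.allclose(sim.v, 0.0)

    def test_rows_stay_sorted_after_crossing(self, straight40):
        sim = make_sim(straight40)
        sim.x = np.tile([[10.0, 11.0]], (8, 1))
        sim.v = np.tile([[2.0, -2.0]], (8, 1))
        sim.pbest = sim.x.copy()
        sim._set_pair_index(4)
        sim.f_p = sim._energies(sim.pbest)
        sim.update_position()
        assert np.all(np.diff(sim.x, axis=1) >= 0)


class TestBestUpdates:
    def test_equal_energy_keeps_old_personal_best(self, straight40):
        sim = make_sim(straight40)
        old_pbest = sim.pbest.copy()
        # nothing moved: f(r) == f(p) exactly, strict inequality keeps p
        sim.update_bests()
        assert np.array_equal(sim.pbest, old_pbest)

    def test_tie_for_global_best_prefers_lower_index(self, straight40):
        sim = make_sim(straight40)
        sim.x = np.tile([[20.0]], (8, 1))  # identical members, identical f
        sim.pbest = sim.x.copy()
        sim.f_p = sim._energies(sim.pbest)
        sim.f_g = np.inf
        sim.update_bests()
        assert np.allclose(sim.gbest, sim.pbest[0])

    def test_worsened_positions_leave_bests_unchanged(self, straight40):
        sim = make_sim(straight40)
        f_p0, f_g0 = sim.f_p.copy(), sim.f_g
        sim.x = np.full((8, 1), 40.0 - 1e-4)  # nearly on the endpoint: awful energy
        sim.update_bests()
        assert np.array_equal(sim.f_p, f_p0)
        assert sim.f_g == f_g0


class TestEnergyStateTransition:
    def test_small_gaps_produce_no_proposals(self, straight40):
        sim = make_sim(
            straight40,
            energy=EnergyParams(ideal_distance=1.1, search_distance=45.0),
        )
        n0 = sim.x.shape[1]
        added = sim.energy_state_transition()
        assert added == 0
        assert sim.x.shape[1] == n0

    def test_wide_gap_recruits_into_every_member(self):
        curve = build_curve(CurveSpec(length=2.2))  # endpoints at 2 r_m
        sim = make_sim(curve, SwarmParams(swarm_size=8, t_max=5))
        # empty the interior so the only segment is the full 2 r_m gap
        sim.x = np.empty((8, 0))
        sim.v = np.empty((8, 0))
        sim.pbest = sim.x.copy()
        sim.gbest = np.empty(0)
        sim._set_pair_index(2)
        sim.f_p = sim._energies(sim.pbest)
        sim.f_g = sim._energy_single(sim.gbest)
        f_before = sim.f_g
        added = sim.energy_state_transition()
        assert added == 1
        assert sim.x.shape[1] == 1
        assert sim.gbest.shape == (1,)
        assert sim.f_g < f_before  # accepted recruitment strictly lowers f(g)

    def test_repulsive_gap_rejects_candidates(self):
        # gap of 1.2 r_m: any interior candidate sits on the repulsive branch
        curve = build_curve(CurveSpec(length=1.2 * 1.1))
        sim = make_sim(curve, SwarmParams(swarm_size=8, t_max=5))
        sim.x = np.empty((8, 0))
        sim.v = np.empty((8, 0))
        sim.pbest = sim.x.copy()
        sim.gbest = np.empty(0)
        sim._set_pair_index(2)
        sim.f_p = sim._energies(sim.pbest)
        sim.f_g = sim._energy_single(sim.gbest)
        assert sim.energy_state_transition() == 0


class TestRunSimulation:
    def test_single_iteration_runs_one_cycle(self, straight40):
        res = run_simulation(straight40, ENERGY, SwarmParams(swarm_size=8, t_max=1),
                             seed=5)
        assert len(res.series["t"]) == 1

    def test_boundary_safety_and_synchronized_growth(self, straight40):
        params = SwarmParams(swarm_size=10, t_max=60)
        sim = SwarmSimulation(straight40, ENERGY, params,
                              rng=np.random.default_rng(2))
        sim.initialize()
        for _ in range(params.t_max):
            sim.step()
            assert np.all((sim.x >= 0.0) & (sim.x <= 40.0))
            assert sim.pbest.shape == sim.x.shape
            assert sim.gbest.shape == (sim.x.shape[1],)

    def test_global_best_energy_never_increases(self, straight40):
        res = run_simulation(straight40, ENERGY, SwarmParams(swarm_size=10, t_max=80),
                             seed=3)
        assert np.all(np.diff(res.series["f_g"]) <= 1e-9)

    def test_cluster_count_never_decreases(self, straight40):
        res = run_simulation(straight40, ENERGY, SwarmParams(swarm_size=10, t_max=80),
                             seed=3)
        assert np.all(np.diff(res.series["n_clusters"]) >= 0)

    def test_same_seed_reproduces_bit_identical_results(self, straight40):
        params = SwarmParams(swarm_size=10, t_max=60)
        a = run_simulation(straight40, ENERGY, params, seed=11)
        b = run_simulation(straight40, ENERGY, params, seed=11)
        assert np.array_equal(a.series["f_g"], b.series["f_g"])
        assert np.array_equal(a.series["mean_spacing"], b.series["mean_spacing"])
        assert np.array_equal(a.gbest, b.gbest)
        assert np.array_equal(a.swarm_points, b.swarm_points)

    def test_curved_fiber_clusters_lie_on_curve(self, arc2020):
        res = run_simulation(arc2020, ENERGY, SwarmParams(swarm_size=8, t_max=40),
                             seed=7)
        xs, ys = res.gbest[:, 0], res.gbest[:, 1]
        assert np.allclose(ys, arc2020.y_at(xs), atol=1e-9)

    def test_metadata_records_parameters_and_choices(self, straight40):
        res = run_simulation(straight40, ENERGY, SwarmParams(swarm_size=8, t_max=5),
                             seed=1)
        assert res.metadata["energy"]["ideal_distance"] == 1.1
        assert "interpretive_choices" in res.metadata
        assert res.metadata["seed"] == 1
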
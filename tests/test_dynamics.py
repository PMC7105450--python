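"""Integrator, persistence process, neighbour lists and run-loop contracts."""

import math

import numpy as np
import pytest

from ecmigrate.dynamics import (SimulationState, refresh_random_forces, rhs,
                                run, step_rk4_adaptive, _Engine, _rk4)
from ecmigrate.geometry import (CellPopulation, build_obstacles, flat_channel,
                                seed_monolayer)


def _free_population(positions):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    return CellPopulation(positions, np.ones(len(positions), dtype=bool))


class TestRefreshRandomForces:
    def test_zero_rate_never_refreshes(self, params):
        p = params.with_overrides(p_change=0.0)
        state = SimulationState.initialise(_free_population([[0, 0, 0]] * 20), p, 5)
        before = state.population.F_rand.copy()
        for _ in range(100):
            refresh_random_forces(state, p, 0.5)
        np.testing.assert_array_equal(state.population.F_rand, before)

    def test_mean_holding_time_matches_rate(self, params):
        """Exponential persistence: mean holding time 1/p_change = 13.33 h,
        recovered within 5% from 1000 h of simulated refreshes."""
        state = SimulationState.initialise(
            _free_population(np.zeros((200, 3))), params, 9)
        dt, hours = 0.5, 1000.0
        changes = [[] for _ in range(200)]
        prev = state.population.F_rand.copy()
        t = 0.0
        last_change = np.zeros(200)
        holds = []
        while t < hours:
            refresh_random_forces(state, params, dt)
            t += dt
            changed = np.any(state.population.F_rand != prev, axis=1)
            for i in np.nonzero(changed)[0]:
                holds.append(t - last_change[i])
                last_change[i] = t
            prev = state.population.F_rand.copy()
        assert np.mean(holds) == pytest.approx(1 / params.p_change, rel=0.05)

    def test_fixed_seed_reproduces_refresh_pattern(self, params):
        outs = []
        for _ in range(2):
            state = SimulationState.initialise(
                _free_population(np.zeros((30, 3))), params, 77)
            for _ in range(50):
                refresh_random_forces(state, params, 0.5)
            outs.append(state.population.F_rand.copy())
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_oversized_step_is_rejected(self, params):
        state = SimulationState.initialise(_free_population([[0, 0, 0]]), params, 1)
        with pytest.raises(ValueError):
            refresh_random_forces(state, params, 2.0 / params.p_change)


class TestRhs:
    def test_overdamped_contract_velocity_equals_force(self, params):
        geom = flat_channel()
        state = SimulationState.initialise(
            _free_population([[5.0, 0.3, 0.45]]), params, 3)
        state.population.F_rand[0] = [0.05, 0.0, 0.0]
        v = rhs(state, None, params, geom)
        np.testing.assert_allclose(v[0], [0.05, 0, 0], rtol=1e-12)

    def test_immobile_cell_has_zero_velocity(self, params):
        geom = flat_channel()
        pop = CellPopulation(np.array([[5.0, 0.3, 0.45]]), np.array([False]))
        state = SimulationState.initialise(pop, params, 3)
        state.population.F_rand[0] = [0.05, 0.02, 0.0]
        assert np.all(rhs(state, None, params, geom) == 0.0)

    def test_interacting_pair_velocities_are_equal_and_opposite(self, params):
        geom = flat_channel()
        pos = [[5.0, 0.3, 0.4], [5.0 + 1.1 * params.sigma, 0.3, 0.4]]
        state = SimulationState.initialise(_free_population(pos), params, 3)
        state.population.F_rand[:] = 0.0
        v = rhs(state, None, params, geom)
        np.testing.assert_allclose(v[0], -v[1], atol=1e-18)
        assert np.linalg.norm(v[0]) > 0


class _SpringEngine:
    """Overdamped quadratic well dx/dt = -k (x - centre); closed-form decay."""

    def __init__(self, k=2.0, centre=(0.0, 0.0, 0.0)):
        self.k = k
        self.centre = np.asarray(centre, dtype=float)

    def velocities(self, positions, F_rand, mobile, record_flags=False):
        return -self.k * (positions - self.centre)


class TestAdaptiveRK4:
    def test_constant_force_trajectory_is_exact(self, params):
        geom = flat_channel()
        state = SimulationState.initialise(
            _free_population([[5.0, 0.3, 0.45]]), params, 3)
        state.population.F_rand[0] = [0.04, 0.0, 0.0]
        engine = _Engine(geom, None, None, params)
        x0 = state.population.positions[0, 0]
        total = 0.0
        while total < 1.0 - 1e-12:
            state, dt_used, _ = step_rk4_adaptive(
                state, engine, params, 0.05, dt_cap=1.0 - total)
            total += dt_used
        assert state.population.positions[0, 0] == pytest.approx(x0 + 0.04,
                                                                 rel=1e-12)

    def test_spring_decay_matches_closed_form(self, params):
        k = 2.0
        engine = _SpringEngine(k=k)
        state = SimulationState.initialise(
            _free_population([[1.0, 0.5, -0.25]]), params, 3)
        x0 = state.population.positions.copy()
        t_end, t = 1.0, 0.0
        while t < t_end - 1e-12:
            state, dt_used, _ = step_rk4_adaptive(
                state, engine, params, 0.05, dt_cap=t_end - t)
            t += dt_used
        np.testing.assert_allclose(state.population.positions,
                                   x0 * math.exp(-k * t_end), atol=1e-8)

    def test_fourth_order_convergence_on_spring(self, params):
        k = 3.0
        engine = _SpringEngine(k=k)
        x0 = np.array([[1.0, 0.0, 0.0]])
        errs = []
        dts = [0.2, 0.1, 0.05, 0.025]
        for dt in dts:
            pos = x0.copy()
            n = int(round(1.0 / dt))
            for _ in range(n):
                pos = _rk4(engine, pos, None, None, dt)
            errs.append(abs(pos[0, 0] - math.exp(-k)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 3.5) and np.all(orders < 4.6)

    def test_error_estimate_shrinks_with_tolerance(self, params):
        """Tightening tol_abs forces smaller accepted steps on a stiff-ish
        spring, reducing the per-step defect accordingly."""
        k = 40.0
        engine = _SpringEngine(k=k)
        sizes = {}
        for tol in (1e-5, 1e-5 / 16):
            state = SimulationState.initialise(
                _free_population([[1.0, 0.0, 0.0]]), params, 3)
            state, dt_used, _ = step_rk4_adaptive(
                state, engine, params, 0.05, tol_abs=tol)
            sizes[tol] = dt_used
        assert sizes[1e-5 / 16] < sizes[1e-5]

    def test_underflow_raises_stiffness_error(self, params):
        engine = _SpringEngine(k=1e9)
        state = SimulationState.initialise(
            _free_population([[1.0, 0.0, 0.0]]), params, 3)
        with pytest.raises(RuntimeError, match="underflow"):
            step_rk4_adaptive(state, engine, params, 0.05)


class TestNeighbourIndex:
    def test_forces_match_brute_force_on_random_cloud(self, params, rng):
        """Neighbour-list engine vs O(N^2) all-pairs on 100 random cells
        plus an obstacle patch, to 1e-12 relative."""
        from ecmigrate.model_core import pair_force_magnitude

        geom = flat_channel(length=2.0, width=0.5)
        obs = build_obstacles(flat_channel(length=0.5, width=0.5), params)
        positions = np.column_stack([
            rng.uniform(0.05, 0.45, 100), rng.uniform(0.0, 0.06, 100),
            rng.uniform(0.05, 0.45, 100)])
        pop = CellPopulation(positions, np.ones(100, dtype=bool))
        F_rand = rng.normal(scale=0.03, size=(100, 3))

        engine = _Engine(geom, obs, None, params)
        got = engine.velocities(positions, F_rand, pop.mobile)

        want = np.zeros_like(got)
        sources = np.vstack([positions, obs.centres])
        for i in range(100):
            F = F_rand[i].copy()
            for j in range(len(sources)):
                if j == i:
                    continue
                dxv = positions[i] - sources[j]
                r = np.linalg.norm(dxv)
                if r > params.r_cutoff or r == 0:
                    continue
                F += pair_force_magnitude(r, params) * dxv / r
            want[i] = F
        scale = np.abs(want).max()
        np.testing.assert_allclose(got, want, atol=1e-12 * scale)

    def test_numba_and_numpy_force_paths_agree(self, params, rng):
        """The fused numba kernel and the pure-numpy engine path compute the
        same velocities to ~1e-15 relative (fastmath reassociation only)."""
        geom = flat_channel(length=1.0, width=0.5)
        obs = build_obstacles(flat_channel(length=0.4, width=0.5), params)
        positions = np.column_stack([
            rng.uniform(0.05, 0.35, 80), rng.uniform(0, 0.05, 80),
            rng.uniform(0.05, 0.45, 80)])
        F_rand = rng.normal(scale=0.03, size=(80, 3))
        mobile = rng.random(80) < 0.9
        a = _Engine(geom, obs, None, params, use_numba=True).velocities(
            positions, F_rand, mobile)
        b = _Engine(geom, obs, None, params, use_numba=False).velocities(
            positions, F_rand, mobile)
        np.testing.assert_allclose(a, b, rtol=0,
                                   atol=1e-13 * np.abs(b).max())

    def test_index_reuse_does_not_change_forces(self, params, rng):
        geom = flat_channel(length=1.0, width=0.5)
        positions = np.column_stack([
            rng.uniform(0.1, 0.9, 50), rng.uniform(0, 0.05, 50),
            rng.uniform(0.1, 0.4, 50)])
        F_rand = rng.normal(scale=0.03, size=(50, 3))
        mobile = np.ones(50, dtype=bool)
        engine = _Engine(geom, None, None, params)
        engine.velocities(positions, F_rand, mobile)  # build lists here
        shifted = positions + rng.uniform(-1e-4, 1e-4, size=positions.shape)
        b_reused = engine.velocities(shifted, F_rand, mobile)  # stale superset
        fresh = _Engine(geom, None, None, params)
        b_fresh = fresh.velocities(shifted, F_rand, mobile)    # exact lists
        np.testing.assert_allclose(b_reused, b_fresh, rtol=0, atol=1e-15)


@pytest.fixture(scope="module")
def mini_setup(params):
    geom = flat_channel(length=2.0, width=0.45)
    obs = build_obstacles(geom, params)
    pop = seed_monolayer(geom, params, (0.5, 1.0), n_immobile_rows=1)
    return geom, obs, pop


class TestRunLoop:

    def test_zero_hours_returns_seeding(self, params, mini_setup):
        geom, obs, pop = mini_setup
        traj = run(geom, obs, None, pop, params, hours=0.0, seed=4)
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.positions[0], pop.positions)

    def test_identical_seeds_give_identical_trajectories(self, params, mini_setup):
        geom, obs, pop = mini_setup
        t1 = run(geom, obs, None, pop, params, hours=0.5, seed=11)
        t2 = run(geom, obs, None, pop, params, hours=0.5, seed=11)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.times, t2.times)

    def test_different_seeds_diverge(self, params, mini_setup):
        geom, obs, pop = mini_setup
        t1 = run(geom, obs, None, pop, params, hours=0.3, seed=11)
        t2 = run(geom, obs, None, pop, params, hours=0.3, seed=12)
        assert not np.allclose(t1.positions[-1], t2.positions[-1])

    def test_mobile_cells_stay_in_confinement_band(self, params, mini_setup):
        from scipy.spatial import cKDTree

        geom, obs, pop = mini_setup
        traj = run(geom, obs, None, pop, params, hours=1.0, seed=2)
        tree = cKDTree(obs.centres)
        for frame in traj.positions:
            d, _ = tree.query(frame[traj.mobile])
            assert d.max() <= 3 * params.r_cell + 1e-9

    def test_immobile_cells_never_move(self, params, mini_setup):
        geom, obs, pop = mini_setup
        traj = run(geom, obs, None, pop, params, hours=0.5, seed=6)
        frozen = ~traj.mobile
        assert frozen.any()
        np.testing.assert_array_equal(traj.positions[:, frozen],
                                      np.broadcast_to(pop.positions[frozen],
                                                      (traj.n_frames,
                                                       frozen.sum(), 3)))

    def test_checkpoint_restart_reproduces_uninterrupted_run(self, params,
                                                             mini_setup,
                                                             tmp_path):
        """A run checkpointed at mid-time, serialised to JSON (including the
        per-cell RNG streams), reloaded and continued matches the
        uninterrupted run bit-exactly."""
        from ecmigrate.dynamics import SimulationState

        geom, obs, pop = mini_setup
        full = run(geom, obs, None, pop, params, hours=1.0, seed=33)
        half, state = run(geom, obs, None, pop, params, hours=0.5, seed=33,
                          return_state=True)
        ckpt = tmp_path / "state.json"
        state.to_json(ckpt)
        resumed = run(geom, obs, None, None, params, hours=0.5, seed=33,
                      initial_state=SimulationState.from_json(ckpt))
        np.testing.assert_array_equal(resumed.positions[-1],
                                      full.positions[-1])
        np.testing.assert_allclose(resumed.times[-1], full.times[-1],
                                   atol=1e-9)

    def test_zero_flow_displacements_are_isotropic_in_plane(self, params):
        """Without a flow cue the model is rotation-symmetric in the
        substrate plane: Hotelling's T2 on mean (x, z) displacement of
        non-interacting cells must not reject zero drift at alpha = 0.01."""
        from scipy import stats

        n = 400
        rng0 = np.random.default_rng(0)
        positions = np.column_stack([
            rng0.uniform(0, 50, n), np.zeros(n), rng0.uniform(0, 50, n)])
        geom = flat_channel(length=60.0, height=0.5, width=60.0)
        pop = CellPopulation(positions, np.ones(n, dtype=bool))
        traj = run(geom, None, None, pop, params, hours=24.0, seed=21,
                   output_interval=1.0)
        disp = (traj.positions[-1] - traj.positions[0])[:, [0, 2]]
        mean = disp.mean(axis=0)
        cov = np.cov(disp.T)
        t2 = n * mean @ np.linalg.solve(cov, mean)
        fstat = (n - 2) / (2 * (n - 1)) * t2
        pval = stats.f.sf(fstat, 2, n - 2)
        assert pval > 0.01
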
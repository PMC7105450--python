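"""Time integration of the cell population.

The equation of motion is overdamped: the velocity of every mobile cell is
``mobility * F_total`` with mobility 1 mm/h per a.u. (immobile cells never
move).  Integration uses classical RK4 with step-doubling error control;
after each accepted step the monolayer confinement (hard projection onto
the 3 r_cell obstacle band) is applied and each cell's persistent random
force is refreshed with probability ``1 - exp(-p_change * dt)``.

The persistent random force and the flow field are frozen within one RK4
step; the flow *cue direction* is re-sampled at every substep position.

Randomness: one seed per run; each cell owns an independent child stream
derived from it, so population-size changes do not reshuffle unrelated
draws and refresh patterns are reproducible bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (CellPopulation, ChannelGeometry, ObstacleSet,
                       side_wall_force_vec)
from .model_core import ModelParams, pair_force_magnitude_vec
from .trajectory import Trajectory

__all__ = [
    "SimulationState",
    "NeighbourIndex",
    "refresh_random_forces",
    "rhs",
    "step_rk4_adaptive",
    "run",
    "MOBILITY",
    "DT_MIN",
    "DT_MAX",
    "TOL_ABS",
]

MOBILITY = 1.0        # mm/h per a.u. of force
DT_MIN = 1e-5         # h
DT_MAX = 0.05         # h
TOL_ABS = 1e-5        # mm, step-doubling acceptance tolerance

_NOFLAGS = np.zeros(1, dtype=np.uint8)  # placeholder when flags are not recorded


@dataclass
class SimulationState:
    """Mutable state of a run: time, population, per-cell RNG streams, step size."""

    time: float
    population: CellPopulation
    rngs: list                      # one np.random.Generator per cell
    dt: float = DT_MAX
    n_accepted: int = 0             # accepted-step counter (growth probing)

    @classmethod
    def initialise(cls, population: CellPopulation, p: ModelParams,
                   seed: int) -> "SimulationState":
        """Seed per-cell streams and draw the initial persistent forces."""
        children = np.random.SeedSequence(seed).spawn(len(population))
        rngs = [np.random.Generator(np.random.PCG64(c)) for c in children]
        pop = population.copy()
        sd = math.sqrt(p.c_var)
        for i, rng in enumerate(rngs):
            pop.F_rand[i] = rng.normal(0.0, sd, size=3)
        return cls(time=0.0, population=pop, rngs=rngs)

    # -- checkpointing: the full state (incl. RNG streams) is serialisable --

    def to_json(self, path) -> None:
        import json

        pop = self.population
        blob = {
            "time": self.time,
            "dt": self.dt,
            "n_accepted": self.n_accepted,
            "positions": pop.positions.tolist(),
            "mobile": pop.mobile.astype(int).tolist(),
            "F_rand": pop.F_rand.tolist(),
            "rng_states": [rng.bit_generator.state for rng in self.rngs],
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def from_json(cls, path) -> "SimulationState":
        import json

        with open(path) as fh:
            blob = json.load(fh)
        pop = CellPopulation(np.asarray(blob["positions"], dtype=float),
                             np.asarray(blob["mobile"], dtype=bool),
                             np.asarray(blob["F_rand"], dtype=float))
        rngs = []
        for st in blob["rng_states"]:
            bg = np.random.PCG64()
            bg.state = st
            rngs.append(np.random.Generator(bg))
        return cls(time=float(blob["time"]), population=pop, rngs=rngs,
                   dt=float(blob["dt"]),
                   n_accepted=int(blob.get("n_accepted", 0)))


class NeighbourIndex:
    """Cutoff-radius neighbour lists for cells and obstacle elements.

    Pair lists are built with a skin margin and reused until any cell has
    moved more than half the skin since the last build, at which point they
    are exact supersets no longer and get rebuilt.  Query results equal the
    brute-force all-pairs neighbourhood (verified in the test suite).
    """

    def __init__(self, obstacles: ObstacleSet | None, p: ModelParams,
                 skin: float | None = None):
        self.p = p
        self.skin = 0.5 * p.r_cell if skin is None else skin
        self.obstacle_centres = (np.asarray(obstacles.centres, dtype=float)
                                 if obstacles is not None and len(obstacles)
                                 else np.zeros((0, 3)))
        self.obstacle_tree = (cKDTree(self.obstacle_centres)
                              if len(self.obstacle_centres) else None)
        self._built_at = None
        self.cc_pairs = np.zeros((0, 2), dtype=int)
        self.co_cell = np.zeros(0, dtype=int)
        self.co_obs = np.zeros(0, dtype=int)

    def update(self, positions: np.ndarray) -> None:
        if self._built_at is not None:
            disp = np.abs(positions - self._built_at).max(initial=0.0)
            if disp <= 0.5 * self.skin:
                return
        r_query = self.p.r_cutoff + self.skin
        cell_tree = cKDTree(positions)
        pairs = cell_tree.query_pairs(r_query, output_type="ndarray")
        self.cc_pairs = pairs if len(pairs) else np.zeros((0, 2), dtype=int)
        if self.obstacle_tree is not None:
            lists = self.obstacle_tree.query_ball_point(positions, r_query)
            counts = np.fromiter((len(l) for l in lists), dtype=int,
                                 count=len(lists))
            self.co_cell = np.repeat(np.arange(len(positions)), counts)
            self.co_obs = (np.concatenate([np.asarray(l, dtype=int)
                                           for l in lists if l])
                           if counts.sum() else np.zeros(0, dtype=int))
        self._built_at = positions.copy()


class _Engine:
    """Vectorised force evaluation for one configured simulation.

    Two equivalent paths: a fused numba kernel (default, used by the run
    loop) and a pure-numpy path kept as an in-package cross-check; both are
    verified against the scalar :func:`ecmigrate.model_core.total_force`.
    """

    def __init__(self, geom: ChannelGeometry, obstacles: ObstacleSet | None,
                 flow_field, p: ModelParams,
                 wall_stiffness: float = 10.0, use_numba: bool = True):
        self.geom = geom
        self.obstacles = obstacles
        self.flow = flow_field
        self.p = p
        self.wall_stiffness = wall_stiffness
        self.use_numba = use_numba
        self.index = NeighbourIndex(obstacles, p)
        self.degenerate_cells: set[int] = set()
        self.coincident_pairs: list[tuple[int, int]] = []

    def total_forces(self, positions: np.ndarray, F_rand: np.ndarray,
                     record_flags: bool = False) -> np.ndarray:
        p = self.p
        n = len(positions)
        F = np.zeros((n, 3))

        # migration force: blend random and flow directions at these positions
        Fmag = np.linalg.norm(F_rand, axis=1)
        nz = Fmag > 0
        e_rand = np.zeros_like(F_rand)
        e_rand[nz] = F_rand[nz] / Fmag[nz, None]
        if self.flow is not None:
            v = self.flow.sample(positions, strict=False)
            speed = np.linalg.norm(v, axis=1)
            has_flow = speed > 1e-15
            w = np.clip(speed / p.v_max, 0.0, 1.0) * (p.w_max - p.w_min) + p.w_min
            e_vel = np.zeros_like(v)
            e_vel[has_flow] = v[has_flow] / speed[has_flow, None]
            d = np.where(has_flow[:, None],
                         e_rand * (1.0 - w[:, None]) + e_vel * w[:, None],
                         e_rand)
        else:
            d = e_rand
        dn = np.linalg.norm(d, axis=1)
        bad = (dn < 1e-12) & nz
        if np.any(bad):
            # anti-parallel cue collapse: fall back to the random direction for
            # this evaluation; the run loop resamples these cells post-step
            d[bad] = e_rand[bad]
            dn[bad] = 1.0
            if record_flags:
                self.degenerate_cells.update(np.nonzero(bad)[0].tolist())
        F[nz] = Fmag[nz, None] * d[nz] / dn[nz, None]

        # pairwise interactions
        self.index.update(positions)
        ij = self.index.cc_pairs
        if len(ij):
            dx = positions[ij[:, 0]] - positions[ij[:, 1]]
            r = np.linalg.norm(dx, axis=1)
            ok = (r <= p.r_cutoff) & (r > 1e-9)
            if record_flags and np.any((r <= 1e-9)):
                for a, b in ij[r <= 1e-9]:
                    self.coincident_pairs.append((int(a), int(b)))
            if np.any(ok):
                fij = (pair_force_magnitude_vec(r[ok], p) / r[ok])[:, None] * dx[ok]
                for c in range(3):
                    F[:, c] += np.bincount(ij[ok, 0], weights=fij[:, c], minlength=n)
                    F[:, c] -= np.bincount(ij[ok, 1], weights=fij[:, c], minlength=n)
        ci, oi = self.index.co_cell, self.index.co_obs
        if len(ci):
            dx = positions[ci] - self.index.obstacle_centres[oi]
            r = np.linalg.norm(dx, axis=1)
            ok = (r <= p.r_cutoff) & (r > 1e-9)
            if np.any(ok):
                fio = (pair_force_magnitude_vec(r[ok], p) / r[ok])[:, None] * dx[ok]
                for c in range(3):
                    F[:, c] += np.bincount(ci[ok], weights=fio[:, c], minlength=n)

        F += side_wall_force_vec(positions, self.geom, self.wall_stiffness)
        if not np.isfinite(F).all():
            bad_cell = int(np.nonzero(~np.isfinite(F).all(axis=1))[0][0])
            raise FloatingPointError(f"non-finite force on cell {bad_cell}")
        return F

    def velocities(self, positions: np.ndarray, F_rand: np.ndarray,
                   mobile: np.ndarray, record_flags: bool = False) -> np.ndarray:
        if not self.use_numba:
            v = MOBILITY * self.total_forces(positions, F_rand, record_flags)
            v[~mobile] = 0.0
            return v
        from ._kernels import velocities_kernel

        p = self.p
        self.index.update(positions)
        cc = self.index.cc_pairs
        if self.flow is not None:
            ux, uy, delta, has_flow = (self.flow.ux, self.flow.uy,
                                       self.flow.delta, True)
        else:
            ux = uy = np.zeros((2, 2))
            delta, has_flow = 1.0, False
        if record_flags:
            deg = np.zeros(len(positions), dtype=np.uint8)
            coin = np.zeros(max(1, len(cc)), dtype=np.uint8)
        else:
            deg = coin = _NOFLAGS
        v = velocities_kernel(
            positions, F_rand, mobile, cc, self.index.co_cell,
            self.index.co_obs, self.index.obstacle_centres,
            ux, uy, delta, has_flow,
            p.r_cell, p.C, p.epsilon, p.contact_area_variant == "caption",
            p.v_max, p.w_min, p.w_max,
            self.geom.width, self.wall_stiffness, MOBILITY,
            deg, coin, record_flags)
        if record_flags:
            if deg.any():
                self.degenerate_cells.update(np.nonzero(deg)[0].tolist())
            if len(cc) and coin[:len(cc)].any():
                for a, b in cc[coin[:len(cc)].astype(bool)]:
                    self.coincident_pairs.append((int(a), int(b)))
            # blow-up guard once per step (k1 evaluation) rather than at
            # every substep; non-finite forces propagate to k1 next step
            if not np.isfinite(v).all():
                bad = int(np.nonzero(~np.isfinite(v).all(axis=1))[0][0])
                raise FloatingPointError(f"non-finite force on cell {bad}")
        return v


def refresh_random_forces(state: SimulationState, p: ModelParams,
                          dt: float) -> SimulationState:
    """Refresh each mobile cell's persistent force with prob ``1 - exp(-p_change dt)``.

    The exact exponential form makes the refresh statistics independent of
    the step size; ``p_change * dt`` must stay below 0.1 so persistence is
    resolved by the stepping.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if p.p_change * dt >= 0.1:
        raise ValueError("p_change * dt must be below 0.1; reduce the step size")
    prob = 1.0 - math.exp(-p.p_change * dt)
    if prob == 0.0:
        return state
    pop = state.population
    sd = math.sqrt(p.c_var)
    for i in np.nonzero(pop.mobile)[0]:
        rng = state.rngs[i]
        if rng.random() < prob:
            pop.F_rand[i] = rng.normal(0.0, sd, size=3)
    return state


def rhs(state: SimulationState, flow_or_engine, p: ModelParams | None = None,
        geom: ChannelGeometry | None = None,
        obstacles: ObstacleSet | None = None) -> np.ndarray:
    """Per-cell velocity vectors (mm/h) at the current state.

    Accepts either a prepared ``_Engine`` or a flow field plus geometry /
    obstacles from which one is built.
    """
    if isinstance(flow_or_engine, _Engine):
        engine = flow_or_engine
    else:
        if p is None or geom is None:
            raise ValueError("rhs needs params and geometry when not given an engine")
        engine = _Engine(geom, obstacles, flow_or_engine, p)
    pop = state.population
    return engine.velocities(pop.positions, pop.F_rand, pop.mobile)


def _rk4(engine: _Engine, positions, F_rand, mobile, dt, record_flags=False,
         k1=None):
    if k1 is None:
        k1 = engine.velocities(positions, F_rand, mobile, record_flags)
    k2 = engine.velocities(positions + 0.5 * dt * k1, F_rand, mobile)
    k3 = engine.velocities(positions + 0.5 * dt * k2, F_rand, mobile)
    k4 = engine.velocities(positions + dt * k3, F_rand, mobile)
    return positions + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def step_rk4_adaptive(state: SimulationState, engine: _Engine,
                      p: ModelParams, dt_try: float,
                      tol_abs: float = TOL_ABS,
                      dt_min: float = DT_MIN, dt_max: float = DT_MAX,
                      dt_cap: float | None = None):
    """One accepted RK4 step with step-doubling error control.

    Compares one full step against two half steps; accepts when the maximum
    per-cell position discrepancy is below ``tol_abs`` and returns the
    two-half-step solution.  The next step size follows the standard
    4th-order factor ``0.9 (tol/err)^{1/5}``, clamped to
    ``[dt_min, dt_max]``.  ``dt_cap`` additionally limits this step (used to
    land exactly on output frames).  Confinement and wall handling are the
    caller's post-step responsibility.
    """
    if dt_try <= 0:
        raise ValueError("dt_try must be positive")
    pop = state.population
    dt = min(dt_try, dt_max if dt_cap is None else min(dt_max, dt_cap))
    dt = max(dt, dt_min)
    # the full step and the first half step share the same starting state,
    # hence the same k1 evaluation
    k1 = engine.velocities(pop.positions, pop.F_rand, pop.mobile,
                           record_flags=True)
    while True:
        y_full = _rk4(engine, pop.positions, pop.F_rand, pop.mobile, dt,
                      k1=k1)
        y_half = _rk4(engine, pop.positions, pop.F_rand, pop.mobile, 0.5 * dt,
                      k1=k1)
        y_half = _rk4(engine, y_half, pop.F_rand, pop.mobile, 0.5 * dt)
        err = np.abs(y_half - y_full).max(initial=0.0)
        if err < tol_abs:
            # growth is probed only every few accepted steps, with a
            # deadband: the error estimate is noisy where the flow cue
            # crosses grid-cell boundaries, and eager growth buys mostly
            # rejections (each costing a full step-doubling chain) there
            state.n_accepted += 1
            if err < 0.6 * tol_abs and state.n_accepted % 5 == 0:
                factor = (1.5 if err == 0.0
                          else min(1.5, 0.9 * (tol_abs / err) ** 0.2))
            else:
                factor = 1.0
            dt_next = min(max(factor * dt, dt_min), dt_max)
            pop.positions = y_half
            state.time += dt
            state.dt = dt_next
            return state, dt, dt_next
        if dt <= dt_min * (1 + 1e-9):
            raise RuntimeError(
                f"step size underflow at t={state.time:.6f} h: "
                f"error {err:.3e} mm exceeds tol {tol_abs:.1e} at dt={dt:.2e}")
        dt = max(dt * max(0.3, 0.9 * (tol_abs / err) ** 0.2), dt_min)


def run(geom: ChannelGeometry, obstacles: ObstacleSet | None,
        flow_field, population: CellPopulation, p: ModelParams,
        hours: float, seed: int,
        output_interval: float = 0.1,
        tol_abs: float = TOL_ABS,
        wall_stiffness: float = 10.0,
        meta: dict | None = None,
        initial_state: SimulationState | None = None,
        return_state: bool = False):
    """Advance the population for ``hours`` and record frames every
    ``output_interval`` hours (frame times are exact multiples).

    Reproducible bit-exactly for identical inputs and seed.  Passing an
    ``initial_state`` (e.g. loaded from a checkpoint written by
    :meth:`SimulationState.to_json`) resumes a run: the continuation
    reproduces the uninterrupted run bit-exactly.  With ``return_state``
    the final state is returned alongside the trajectory.
    """
    if hours < 0:
        raise ValueError("hours must be non-negative")
    if initial_state is None:
        state = SimulationState.initialise(population, p, seed)
        dt_next = min(DT_MAX, output_interval)
    else:
        state = initial_state
        population = state.population
        dt_next = state.dt
    engine = _Engine(geom, obstacles, flow_field, p, wall_stiffness)
    obstacle_tree = engine.index.obstacle_tree
    sd = math.sqrt(p.c_var)

    t_end = state.time + hours
    frames = [state.population.positions.copy()]
    times = [state.time]
    next_out = state.time + output_interval
    eps = 1e-12
    while state.time < t_end - eps:
        cap = min(next_out, t_end) - state.time
        state, dt_used, dt_next = step_rk4_adaptive(
            state, engine, p, dt_next, tol_abs=tol_abs, dt_cap=cap)

        pop = state.population
        # reflecting monolayer confinement: project escapees back onto the
        # 3 r_cell band and mirror the outward component of their persistent
        # force.  A sliding (absorbing) projection would pin cells at the
        # band edge for the whole persistence time and drain ~20% of the
        # measured migration speed, breaking the ~50 µm/h calibration that
        # the random-force variance encodes; reflection preserves the
        # Maxwell speed distribution.
        if obstacle_tree is not None:
            dist, idx = obstacle_tree.query(pop.positions)
            band = 3.0 * p.r_cell
            escaped = (dist > band) & pop.mobile
            if np.any(escaped):
                nearest = engine.index.obstacle_centres[idx[escaped]]
                normal = (pop.positions[escaped] - nearest) / dist[escaped, None]
                # specular fold: the overshoot beyond the band comes back
                # inside, clamped so deep escapes cannot overfold
                inside = np.maximum(2.0 * band - dist[escaped], 0.5 * band)
                pop.positions[escaped] = nearest + inside[:, None] * normal
                f_out = np.einsum("ij,ij->i", pop.F_rand[escaped], normal)
                flip = f_out > 0
                if np.any(flip):
                    sub = pop.F_rand[escaped]
                    sub[flip] -= 2.0 * f_out[flip, None] * normal[flip]
                    pop.F_rand[escaped] = sub
        # coincident-centre handling: nudge one partner apart (seeded)
        if engine.coincident_pairs:
            for (a, b) in engine.coincident_pairs:
                i = a if pop.mobile[a] else b
                u = state.rngs[i].normal(size=3)
                pop.positions[i] += 1e-6 * p.r_cell * u / np.linalg.norm(u)
            engine.coincident_pairs.clear()
        # degenerate blended direction: resample that cell's random force
        if engine.degenerate_cells:
            for i in engine.degenerate_cells:
                if pop.mobile[i]:
                    pop.F_rand[i] = state.rngs[i].normal(0.0, sd, size=3)
            engine.degenerate_cells.clear()
        refresh_random_forces(state, p, dt_used)

        if state.time >= next_out - eps:
            frames.append(pop.positions.copy())
            snapped = round(state.time / output_interval) * output_interval
            times.append(snapped if abs(snapped - state.time) < 1e-9
                         else state.time)
            next_out = times[-1] + output_interval

    info = {"seed": seed, "hours": hours, "output_interval_h": output_interval,
            "geometry_kind": geom.kind, "n_cells": len(population),
            "n_mobile": population.n_mobile}
    if meta:
        info.update(meta)
    traj = Trajectory(np.array(times), np.array(frames),
                      state.population.mobile.copy(), info)
    if return_state:
        return traj, state
    return traj
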
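"""Pairwise forces and the migration rule for the endothelial-cell particle model.

Every endothelial cell (EC) is a spherical particle of radius ``r_cell``.
Cells (and the fixed obstacle elements that tile the substrate, ridges and
step faces) interact through a truncated Lennard-Jones 12/6 tail for
non-overlapping nearby particles and a finite neo-Hookean soft-core
repulsion for overlapping ones.  Migration is a persistent random walk whose
direction is blended with the local flow direction: the blending weight
grows linearly with the local flow speed between ``w_min`` (no flow) and
``w_max`` (at or above ``v_max``).

Sign convention
---------------
``pair_force_magnitude`` returns the signed force along the centre line
joining two particles, *positive = repulsive*.  Under this convention the
Lennard-Jones branch is attractive (negative) for ``sigma < r < r_cutoff``,
zero at the equilibrium distance ``sigma = 2 r_cell``, and the soft-core
branch is repulsive (positive) for overlapping particles.

Working units: lengths in mm, time in hours, forces in arbitrary units
(a.u.).  With the overdamped mobility of 1 mm/h per a.u. used by
:mod:`ecmigrate.dynamics`, the mean random-force magnitude
``sqrt(8 c / pi) ~ 0.048 a.u.`` yields the calibrated migration speed of
about 50 µm/h.  Flow speeds stay in m/s: they enter only through the ratio
``v / v_max`` and the flow unit vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "contact_area",
    "pair_force_magnitude",
    "velocity_weight",
    "migration_direction",
    "migration_force",
    "total_force",
    "sample_random_force",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the cell-migration model (single source of truth).

    Defaults are the published calibration for human ECs in a flow chamber.

    Attributes
    ----------
    r_cell:
        Cell radius in mm (15 µm).
    C:
        Elastic constant of the soft-core repulsion, a.u.
    epsilon:
        Lennard-Jones interaction constant, a.u.
    v_max:
        Flow speed (m/s) above which the flow-cue weight saturates at
        ``w_max``.  Chosen so that the corresponding first-node wall shear
        stress is 2.4 Pa.
    w_min, w_max:
        Minimum / maximum weight of the flow-velocity direction in the
        migration-direction blend.  ``w_min`` drops to 0.05 in the
        ROCK-inhibition scenario.
    c_var:
        Variance of each Cartesian component of the persistent random
        force, a.u.².
    p_change:
        Rate (per hour) at which a cell's persistent random force is
        replaced by a fresh draw.
    nu_dyn:
        Dynamic viscosity of the perfusing fluid, Pa·s.
    delta:
        Flow-lattice spacing, mm.
    contact_area_variant:
        ``"printed"`` uses a = sqrt((r_cell/2)(2 r_cell - r));
        ``"caption"`` uses a = sqrt(r_cell (2 r_cell - r)), which reproduces
        the documented 1.658e-3 a.u. repulsion at complete overlap.
    """

    r_cell: float = 0.015
    C: float = 0.1
    epsilon: float = 3e-7
    v_max: float = 0.036
    w_min: float = 0.3
    w_max: float = 0.7
    c_var: float = 9e-4
    p_change: float = 0.075
    nu_dyn: float = 1e-3
    delta: float = 0.015
    rho_fluid: float = 1000.0  # kg/m^3, Reynolds reporting only
    contact_area_variant: str = "printed"

    # derived lengths
    @property
    def sigma(self) -> float:
        """Equilibrium distance where the interaction force vanishes (= 2 r_cell)."""
        return 2.0 * self.r_cell

    @property
    def r_cutoff(self) -> float:
        """Maximum interaction distance (= 4 r_cell)."""
        return 4.0 * self.r_cell

    def __post_init__(self) -> None:
        if self.r_cell <= 0:
            raise ValueError("r_cell must be positive")
        if not (0.0 <= self.w_min <= self.w_max <= 1.0):
            raise ValueError("weights must satisfy 0 <= w_min <= w_max <= 1")
        if self.c_var <= 0:
            raise ValueError("c_var must be positive")
        if self.p_change < 0:
            raise ValueError("p_change must be non-negative")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.contact_area_variant not in ("printed", "caption"):
            raise ValueError("contact_area_variant must be 'printed' or 'caption'")

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def contact_area(r: float, p: ModelParams) -> float:
    """Approximate contact length scale of two overlapping spheres at centre distance *r*.

    The default (``printed``) form is ``sqrt((r_cell/2)(2 r_cell - r))``,
    equal to ``r_cell`` at complete overlap.  The ``caption`` variant
    ``sqrt(r_cell (2 r_cell - r))`` is available on the parameter object.
    """
    r_cell = p.r_cell
    if not (0.0 <= r < 2.0 * r_cell):
        raise ValueError(f"contact_area requires 0 <= r < 2*r_cell, got r={r!r}")
    if p.contact_area_variant == "caption":
        return math.sqrt(r_cell * (2.0 * r_cell - r))
    return math.sqrt(0.5 * r_cell * (2.0 * r_cell - r))


def _soft_core(r: float, p: ModelParams) -> float:
    """Neo-Hookean soft-core repulsion (positive) for overlapping particles."""
    a = contact_area(r, p)
    r_cell = p.r_cell
    num = 8.0 * a**3 * p.C * (16.0 * a**2 - 36.0 * math.pi * a * r_cell
                              + 27.0 * math.pi**2 * r_cell**2)
    den = 3.0 * r_cell * (4.0 * a - 3.0 * math.pi * r_cell) ** 2
    return num / den


def pair_force_magnitude(r: float, p: ModelParams) -> float:
    """Signed interaction force along the centre line (positive = repulsive).

    Three branches: neo-Hookean soft core for ``r < 2 r_cell``; truncated
    Lennard-Jones 12/6 (attractive) for ``2 r_cell <= r <= r_cutoff``; zero
    beyond the cut-off.  Both inner branches vanish at the equilibrium
    distance ``sigma = 2 r_cell``, making the force continuous there.
    """
    if r <= 0.0:
        raise ValueError("pair_force_magnitude requires r > 0 (coincident centres)")
    if r > p.r_cutoff:
        return 0.0
    if r < p.sigma:
        return _soft_core(r, p)
    s6 = (p.sigma / r) ** 6
    return 48.0 * p.epsilon * (s6 * s6 - s6)


def velocity_weight(v: float, p: ModelParams) -> float:
    """Weight of the flow direction in the migration blend, linear in ``v`` up to ``v_max``."""
    if v < 0.0:
        raise ValueError("flow speed must be non-negative")
    if v >= p.v_max:
        return p.w_max
    return (v / p.v_max) * (p.w_max - p.w_min) + p.w_min


def migration_direction(e_rand, e_vel, w: float):
    """Blend the random-walk and flow unit vectors: ``d = (1-w) e_rand + w e_vel``.

    The result is *not* renormalised here (|d| <= 1); the migration force
    divides by |d|.  A zero-length input vector is a domain error.
    """
    e_rand = np.asarray(e_rand, dtype=float)
    e_vel = np.asarray(e_vel, dtype=float)
    if np.linalg.norm(e_rand) == 0.0 or np.linalg.norm(e_vel) == 0.0:
        raise ValueError("migration_direction requires non-zero input vectors")
    if not (0.0 <= w <= 1.0):
        raise ValueError("weight must lie in [0, 1]")
    return e_rand * (1.0 - w) + e_vel * w


def migration_force(F_rand, d):
    """Migration force: magnitude of the persistent random force along ``d / |d|``."""
    F_rand = np.asarray(F_rand, dtype=float)
    d = np.asarray(d, dtype=float)
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise ValueError("degenerate blended direction (|d| < 1e-12); resample e_rand")
    return np.linalg.norm(F_rand) * d / nd


def sample_random_force(rng: np.random.Generator, p: ModelParams):
    """Draw a persistent random force: three N(0, c_var) components.

    The magnitude then follows a Maxwell-Boltzmann-type distribution with
    mean ``sqrt(8 c_var / pi)``.
    """
    return rng.normal(0.0, math.sqrt(p.c_var), size=3)


def _flow_cue(F_rand, v_vec, p: ModelParams, rng: np.random.Generator | None = None):
    """Blended migration force given a flow velocity sample (m/s).

    Zero flow speed degenerates the blend to the pure random direction.  If
    the blended direction collapses (anti-parallel cue at w = 0.5), a fresh
    random direction is drawn when an ``rng`` is supplied, else an error
    propagates.
    """
    F_rand = np.asarray(F_rand, dtype=float)
    v_vec = np.asarray(v_vec, dtype=float)
    Fmag = np.linalg.norm(F_rand)
    if Fmag == 0.0:
        return np.zeros(3)
    speed = np.linalg.norm(v_vec)
    if speed < 1e-15:
        return F_rand.copy()
    w = velocity_weight(speed, p)
    e_rand = F_rand / Fmag
    e_vel = v_vec / speed
    d = migration_direction(e_rand, e_vel, w)
    while np.linalg.norm(d) < 1e-12:
        if rng is None:
            raise ValueError("degenerate blended direction and no rng to resample")
        e_rand = sample_random_force(rng, p)
        e_rand /= np.linalg.norm(e_rand)
        d = migration_direction(e_rand, e_vel, w)
    return Fmag * d / np.linalg.norm(d)


def total_force(i: int, population, obstacles, flow_sample, p: ModelParams):
    """Total force on cell *i*: migration force plus pairwise interactions.

    The neighbourhood is every other cell and every obstacle element within
    ``r_cutoff``.  Obstacle elements exert force on cells but receive none.
    This is the scalar reference implementation; the dynamics layer uses a
    vectorised, neighbour-list equivalent verified against it.

    Parameters
    ----------
    population:
        Object with ``positions`` (N, 3) and ``F_rand`` (N, 3) arrays
        (e.g. :class:`ecmigrate.geometry.CellPopulation`).
    obstacles:
        Object with ``centres`` (M, 3), or None.
    flow_sample:
        Local flow velocity vector (m/s) at the cell position.
    """
    pos = np.asarray(population.positions, dtype=float)
    xi = pos[i]
    F = _flow_cue(population.F_rand[i], flow_sample, p)

    others = np.vstack([np.delete(pos, i, axis=0)] +
                       ([np.asarray(obstacles.centres, dtype=float)]
                        if obstacles is not None and len(obstacles.centres) else []))
    for xj in others:
        dx = xi - xj
        r = np.linalg.norm(dx)
        if r > p.r_cutoff or r == 0.0:
            continue
        F = F + pair_force_magnitude(r, p) * dx / r
    return F


# -- vectorised pair-force kernel (used by dynamics; tested against the scalar path) --

def pair_force_magnitude_vec(r: np.ndarray, p: ModelParams) -> np.ndarray:
    """Vectorised :func:`pair_force_magnitude` (r > 0 assumed)."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    sigma = p.sigma
    lj = (r >= sigma) & (r <= p.r_cutoff)
    if np.any(lj):
        s6 = (sigma / r[lj]) ** 6
        out[lj] = 48.0 * p.epsilon * (s6 * s6 - s6)
    sc = r < sigma
    if np.any(sc):
        r_cell = p.r_cell
        if p.contact_area_variant == "caption":
            a = np.sqrt(r_cell * (2.0 * r_cell - r[sc]))
        else:
            a = np.sqrt(0.5 * r_cell * (2.0 * r_cell - r[sc]))
        num = 8.0 * a**3 * p.C * (16.0 * a**2 - 36.0 * np.pi * a * r_cell
                                  + 27.0 * np.pi**2 * r_cell**2)
        den = 3.0 * r_cell * (4.0 * a - 3.0 * np.pi * r_cell) ** 2
        out[sc] = num / den
    return out
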
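"""Channel geometries, obstacle-element lattices and cell seeding.

The simulated domain is a rectangular flow channel.  Coordinates:
``x`` streamwise (inlet at x = 0), ``y`` wall-normal (substrate at y = 0),
``z`` spanwise.  All positions are particle centres, in mm.

Wetted solid surfaces (the bottom substrate, ridge faces representing stent
struts, the backward-step face) are tiled with *obstacle elements*: fixed,
highly overlapping spheres of radius ``r_cell`` on a hexagonal lattice with
nearest-neighbour spacing ``r_cell``.  Cells interact with them through the
same pair force as with each other, and the monolayer constraint restricts
every mobile cell centre to within ``3 r_cell`` of the nearest obstacle
element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model_core import ModelParams

__all__ = [
    "ChannelGeometry",
    "ObstacleSet",
    "CellPopulation",
    "build_obstacles",
    "seed_monolayer",
    "confinement_violation",
    "side_wall_force",
    "ridged_channel",
    "step_channel",
    "flat_channel",
]


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular channel with optional ridges or a backward-facing step.

    ``kind`` is one of ``flat``, ``ridged``, ``backward_step``.  Ridges are
    (x_position, width, height) triples, x_position being the upstream face.
    For ``backward_step``, ``step`` is (x_position, height): upstream of
    x_position the floor is raised to y = height, dropping to y = 0 at the
    step face, so the channel height expands from ``height - step_height``
    to ``height``.
    """

    length: float
    height: float
    width: float
    kind: str = "flat"
    ridges: tuple = ()
    step: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("flat", "ridged", "backward_step"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if min(self.length, self.height, self.width) <= 0:
            raise ValueError("channel dimensions must be positive")
        for (x0, w, h) in self.ridges:
            if not (0 <= x0 and x0 + w <= self.length):
                raise ValueError("ridge outside the domain")
            if h >= self.height:
                raise ValueError("ridge height must be below the channel height")
        if self.kind == "backward_step":
            if self.step is None:
                raise ValueError("backward_step geometry requires a step")
            xs, hs = self.step
            if not (0 < xs < self.length) or not (0 < hs < self.height):
                raise ValueError("step outside the domain")
        if self.kind == "ridged" and not self.ridges:
            raise ValueError("ridged geometry requires at least one ridge")

    def floor_height(self, x: float) -> float:
        """Local substrate height y_floor(x) (top surface of ridges / upstream shelf)."""
        y = 0.0
        if self.kind == "backward_step" and x <= self.step[0]:
            y = self.step[1]
        for (x0, w, h) in self.ridges:
            if x0 <= x <= x0 + w:
                y = max(y, h)
        return y


@dataclass(frozen=True)
class ObstacleSet:
    """Fixed sphere centres tiling the wetted solid surfaces."""

    centres: np.ndarray  # (M, 3) mm
    element_radius: float

    def __post_init__(self):
        object.__setattr__(self, "centres", np.asarray(self.centres, dtype=float))

    def __len__(self) -> int:
        return len(self.centres)

    def tree(self) -> cKDTree:
        return cKDTree(self.centres)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.centres, columns=["x", "y", "z"])
        df["radius"] = self.element_radius
        df.to_csv(path, index=False)


@dataclass
class CellPopulation:
    """Cell centres, mobility flags and per-cell persistent random forces."""

    positions: np.ndarray          # (N, 3) mm
    mobile: np.ndarray             # (N,) bool
    F_rand: np.ndarray | None = None  # (N, 3) a.u.

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        if self.F_rand is None:
            self.F_rand = np.zeros_like(self.positions)
        else:
            self.F_rand = np.asarray(self.F_rand, dtype=float)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_mobile(self) -> int:
        return int(self.mobile.sum())

    def copy(self) -> "CellPopulation":
        return CellPopulation(self.positions.copy(), self.mobile.copy(),
                              self.F_rand.copy())


def _hex_plane(u0: float, u1: float, v0: float, v1: float, spacing: float):
    """Hexagonal lattice points covering the rectangle [u0,u1] x [v0,v1].

    Rows run along v at successive u positions spaced ``spacing * sqrt(3)/2``,
    with alternate rows offset by half a spacing in v.  Returns an (n, 2)
    array of (u, v) points.  Deterministic: no randomness.
    """
    row_pitch = spacing * math.sqrt(3.0) / 2.0
    n_rows = int(math.floor((u1 - u0) / row_pitch + 1e-9)) + 1
    pts = []
    for i in range(n_rows):
        u = u0 + i * row_pitch
        off = 0.5 * spacing if (i % 2) else 0.0
        n_cols = int(math.floor((v1 - v0 - off) / spacing + 1e-9)) + 1
        if n_cols <= 0:
            continue
        v = v0 + off + spacing * np.arange(n_cols)
        pts.append(np.column_stack([np.full(n_cols, u), v]))
    if not pts:
        raise ValueError("empty lattice region")
    return np.vstack(pts)


def hex_plane_count(extent_u: float, extent_v: float, spacing: float) -> int:
    """Closed-form point count of :func:`_hex_plane` on a rectangle of given extents."""
    row_pitch = spacing * math.sqrt(3.0) / 2.0
    n_rows = int(math.floor(extent_u / row_pitch + 1e-9)) + 1
    total = 0
    for i in range(n_rows):
        off = 0.5 * spacing if (i % 2) else 0.0
        total += max(0, int(math.floor((extent_v - off) / spacing + 1e-9)) + 1)
    return total


def build_obstacles(geom: ChannelGeometry, p: ModelParams) -> ObstacleSet:
    """Tile the substrate and every exposed ridge/step face with obstacle elements.

    Horizontal faces are hexagonal lattices in the x-z plane; vertical faces
    (ridge flanks, the step riser) in the y-z plane.  Spacing ``r_cell``
    everywhere, so no straight gap wider than ``r_cell`` exists on any
    wetted surface.
    """
    s = p.r_cell
    parts = []

    def horizontal(x0, x1, y):
        uv = _hex_plane(x0, x1, 0.0, geom.width, s)
        parts.append(np.column_stack([uv[:, 0], np.full(len(uv), y), uv[:, 1]]))

    def vertical(x, y0, y1):
        uv = _hex_plane(y0, y1, 0.0, geom.width, s)
        parts.append(np.column_stack([np.full(len(uv), x), uv[:, 0], uv[:, 1]]))

    if geom.kind == "backward_step":
        xs, hs = geom.step
        horizontal(0.0, xs, hs)          # upstream shelf
        vertical(xs, 0.0, hs)            # step riser
        horizontal(xs, geom.length, 0.0)  # downstream floor
    else:
        horizontal(0.0, geom.length, 0.0)
        for (x0, w, h) in geom.ridges:
            vertical(x0, 0.0, h)          # upstream flank
            horizontal(x0, x0 + w, h)     # ridge top
            vertical(x0 + w, 0.0, h)      # downstream flank
    return ObstacleSet(np.vstack(parts), element_radius=s)


def seed_monolayer(geom: ChannelGeometry, p: ModelParams,
                   region: tuple[float, float],
                   n_immobile_rows: int = 4,
                   spacing: float | None = None) -> CellPopulation:
    """Seed a hexagonal cell monolayer on the substrate over ``region = (x0, x1)``.

    Cell centres sit ``r_cell`` above the local floor with centre spacing
    ``4 r_cell`` (60 µm).  Rows are constant-x lines; the ``n_immobile_rows``
    leftmost rows (lowest x) are flagged immobile to anchor the sheet at the
    upstream edge.  Deterministic: no randomness.
    """
    if spacing is None:
        spacing = 4.0 * p.r_cell
    x0, x1 = region
    if not (0.0 <= x0 < x1 <= geom.length):
        raise ValueError("seeding region must be a non-empty interval inside the domain")
    uv = _hex_plane(x0, x1, 0.0, geom.width, spacing)
    y = np.array([geom.floor_height(x) + p.r_cell for x in uv[:, 0]])
    positions = np.column_stack([uv[:, 0], y, uv[:, 1]])
    mobile = np.ones(len(positions), dtype=bool)
    if n_immobile_rows > 0:
        row_x = np.unique(np.round(uv[:, 0], 12))
        frozen_x = set(row_x[:n_immobile_rows])
        mobile = np.array([round(x, 12) not in frozen_x for x in uv[:, 0]])
    return CellPopulation(positions, mobile)


def confinement_violation(pos, obstacles: ObstacleSet, p: ModelParams,
                          tree: cKDTree | None = None):
    """Monolayer constraint check for one cell centre.

    Returns ``(violated, correction)`` where ``correction`` is the vector
    that moves ``pos`` to the nearest admissible point (distance exactly
    ``3 r_cell`` from the nearest obstacle centre) when violated, else zero.
    """
    pos = np.asarray(pos, dtype=float)
    if tree is None:
        tree = obstacles.tree()
    dist, idx = tree.query(pos)
    band = 3.0 * p.r_cell
    if dist <= band:
        return False, np.zeros(3)
    nearest = obstacles.centres[idx]
    unit = (pos - nearest) / dist
    return True, nearest + band * unit - pos


def project_confinement(positions: np.ndarray, mobile: np.ndarray,
                        tree: cKDTree, centres: np.ndarray,
                        p: ModelParams) -> np.ndarray:
    """Vectorised hard projection of mobile cells onto the 3 r_cell band."""
    band = 3.0 * p.r_cell
    dist, idx = tree.query(positions)
    out = positions.copy()
    bad = (dist > band) & mobile
    if np.any(bad):
        nearest = centres[idx[bad]]
        unit = (positions[bad] - nearest) / dist[bad, None]
        out[bad] = nearest + band * unit
    return out


def side_wall_force(pos, geom: ChannelGeometry,
                    stiffness: float = 10.0):
    """Frictionless restoring force from the spanwise channel walls.

    Zero inside the channel; a purely z-normal spring force (``stiffness``
    a.u. per mm of penetration) when a cell centre crosses z = 0 or
    z = width.  No tangential component ever.
    """
    pos = np.asarray(pos, dtype=float)
    F = np.zeros(3)
    if pos[2] < 0.0:
        F[2] = -stiffness * pos[2]
    elif pos[2] > geom.width:
        F[2] = -stiffness * (pos[2] - geom.width)
    return F


def side_wall_force_vec(positions: np.ndarray, geom: ChannelGeometry,
                        stiffness: float = 10.0) -> np.ndarray:
    z = positions[:, 2]
    fz = np.where(z < 0.0, -stiffness * z,
                  np.where(z > geom.width, -stiffness * (z - geom.width), 0.0))
    F = np.zeros_like(positions)
    F[:, 2] = fz
    return F


# ----- default geometries for the published scenarios -----

def flat_channel(length: float = 10.0, height: float = 0.5,
                 width: float = 0.9) -> ChannelGeometry:
    """Flat calibration channel (no ridges)."""
    return ChannelGeometry(length, height, width, kind="flat")


def ridged_channel(length: float = 10.0, height: float = 0.5, width: float = 0.9,
                   ridge_width: float = 0.1, ridge_height: float = 0.1,
                   first_ridge_x: float = 5.0, ridge_pitch: float = 1.5,
                   n_ridges: int = 3) -> ChannelGeometry:
    """Ridged flow chamber: three 100 µm struts, the first 5 mm from the inlet."""
    ridges = tuple((first_ridge_x + i * ridge_pitch, ridge_width, ridge_height)
                   for i in range(n_ridges))
    return ChannelGeometry(length, height, width, kind="ridged", ridges=ridges)


def step_channel(length: float = 12.0, height: float = 0.75, width: float = 0.9,
                 step_x: float = 2.0, step_height: float = 0.25) -> ChannelGeometry:
    """Backward-facing step chamber: 0.5 mm inlet section expanding by 0.25 mm,
    step face 2 mm from the inlet."""
    return ChannelGeometry(length, height, width, kind="backward_step",
                           step=(step_x, step_height))
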
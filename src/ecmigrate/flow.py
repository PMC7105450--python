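"""Steady channel-flow fields, velocity sampling, wall shear stress and
recirculation diagnostics.

The flow is solved on the x-y plane of the channel and extruded uniformly
across the spanwise (z) direction.  A D2Q9 BGK lattice-Boltzmann solver with
halfway bounce-back handles the ridged and backward-step geometries; the
flat channel returns the analytic plane-Poiseuille profile directly.

The grid has nodes at ``x = i * delta``, ``y = j * delta`` with ``delta``
the lattice spacing (0.015 mm by default).  Velocities are in m/s; they feed
the cell model only through the flow-cue weight ``v / v_max`` and the flow
unit vector, so no unit conversion to the mm/h mechanics is needed.

Inflow convention: the peak inlet speed defaults to the value that makes the
streamwise speed at the first node above the wall (height ``delta``) equal
to ``v_max`` in the inlet section, which corresponds to the model's 2.4 Pa
wall-shear-stress ceiling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .geometry import ChannelGeometry
from .model_core import ModelParams

__all__ = [
    "FlowField",
    "WSSField",
    "solve_channel_flow",
    "sample_velocity",
    "wall_shear_stress",
    "recirculation_zones",
    "default_peak_speed",
]


@dataclass
class FlowField:
    """Gridded steady velocity field on the channel's x-y plane.

    ``ux``/``uy`` are (nx, ny) arrays (m/s), zero on solid nodes; ``solid``
    marks wall/obstacle nodes.  Sampling is bilinear in x-y and constant
    across z.
    """

    delta: float              # grid spacing, mm
    ux: np.ndarray            # (nx, ny) m/s
    uy: np.ndarray
    solid: np.ndarray         # (nx, ny) bool
    origin: tuple = (0.0, 0.0)
    meta: dict | None = None

    def __post_init__(self):
        self.ux = np.asarray(self.ux, dtype=float)
        self.uy = np.asarray(self.uy, dtype=float)
        self.solid = np.asarray(self.solid, dtype=bool)
        if self.ux.shape != self.uy.shape or self.ux.shape != self.solid.shape:
            raise ValueError("ux, uy and solid must share a shape")
        if not (np.isfinite(self.ux).all() and np.isfinite(self.uy).all()):
            raise ValueError("velocity field contains non-finite values")
        if np.any(self.ux[self.solid] != 0.0) or np.any(self.uy[self.solid] != 0.0):
            raise ValueError("velocities must be zero inside solids")

    @property
    def nx(self) -> int:
        return self.ux.shape[0]

    @property
    def ny(self) -> int:
        return self.ux.shape[1]

    @property
    def extent(self) -> tuple:
        """(x_max, y_max) of the grid, mm."""
        return (self.origin[0] + (self.nx - 1) * self.delta,
                self.origin[1] + (self.ny - 1) * self.delta)

    def sample(self, positions, strict: bool = True) -> np.ndarray:
        """Bilinear velocity sample (m/s) at (N, 3) or (3,) positions in mm.

        Constant across z.  Solid nodes contribute zero, so the
        interpolant decays to zero at walls.  ``strict=True`` raises for
        positions outside the grid bounding box; ``strict=False`` returns
        zero there (used by the dynamics layer, whose confinement band lets
        cells dip marginally below the substrate plane).
        """
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        gx = (pos[:, 0] - self.origin[0]) / self.delta
        gy = (pos[:, 1] - self.origin[1]) / self.delta
        inside = ((gx >= 0) & (gx <= self.nx - 1) &
                  (gy >= 0) & (gy <= self.ny - 1))
        if strict and not inside.all():
            raise ValueError("position outside the flow domain")
        gxc = np.clip(gx, 0, self.nx - 1 - 1e-12)
        gyc = np.clip(gy, 0, self.ny - 1 - 1e-12)
        i0 = gxc.astype(int)
        j0 = gyc.astype(int)
        fx = gxc - i0
        fy = gyc - j0
        out = np.zeros((len(pos), 3))
        for comp, arr in ((0, self.ux), (1, self.uy)):
            v00 = arr[i0, j0]
            v10 = arr[i0 + 1, j0]
            v01 = arr[i0, j0 + 1]
            v11 = arr[i0 + 1, j0 + 1]
            out[:, comp] = ((1 - fx) * (1 - fy) * v00 + fx * (1 - fy) * v10 +
                            (1 - fx) * fy * v01 + fx * fy * v11)
        out[~inside] = 0.0
        if np.asarray(positions).ndim == 1:
            return out[0]
        return out

    # -- near-wall profile along the bottom wall --

    def first_fluid_j(self) -> np.ndarray:
        """Index of the first fluid node above the bottom wall, per column (-1 if none)."""
        out = np.full(self.nx, -1, dtype=int)
        for i in range(self.nx):
            fluid = np.nonzero(~self.solid[i])[0]
            if len(fluid):
                out[i] = fluid[0]
        return out

    def near_wall_ux(self) -> tuple[np.ndarray, np.ndarray]:
        """(x coordinates, streamwise velocity at the first fluid node) along the floor."""
        jj = self.first_fluid_j()
        x = self.origin[0] + np.arange(self.nx) * self.delta
        u = np.array([self.ux[i, jj[i]] if jj[i] >= 0 else 0.0
                      for i in range(self.nx)])
        return x, u

    # -- plain-text round-trip --

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# delta_mm={self.delta!r} origin={self.origin[0]!r},"
                     f"{self.origin[1]!r} nx={self.nx} ny={self.ny}\n")
            fh.write("x_index,y_index,ux,uy,mask\n")
            for i in range(self.nx):
                for j in range(self.ny):
                    fh.write(f"{i},{j},{float(self.ux[i, j])!r},"
                             f"{float(self.uy[i, j])!r},"
                             f"{int(self.solid[i, j])}\n")

    @classmethod
    def from_csv(cls, path) -> "FlowField":
        with open(path) as fh:
            header = fh.readline()
            body = fh.read()
        kv = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        delta = float(kv["delta_mm"])
        ox, oy = (float(v) for v in kv["origin"].split(","))
        nx, ny = int(kv["nx"]), int(kv["ny"])
        data = np.genfromtxt(io.StringIO(body), delimiter=",", skip_header=1)
        ux = np.zeros((nx, ny))
        uy = np.zeros((nx, ny))
        solid = np.zeros((nx, ny), dtype=bool)
        ii = data[:, 0].astype(int)
        jj = data[:, 1].astype(int)
        ux[ii, jj] = data[:, 2]
        uy[ii, jj] = data[:, 3]
        solid[ii, jj] = data[:, 4] > 0.5
        return cls(delta, ux, uy, solid, origin=(ox, oy))


@dataclass
class WSSField:
    """Wall shear stress (Pa) at bottom-wall-adjacent nodes, first-node gradient rule."""

    x: np.ndarray        # mm, per wall column
    wss: np.ndarray      # Pa, non-negative magnitudes

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.wss = np.asarray(self.wss, dtype=float)
        if np.any(self.wss < 0):
            raise ValueError("WSS magnitudes must be non-negative")


def default_peak_speed(geom: ChannelGeometry, p: ModelParams) -> float:
    """Peak inlet speed (m/s) making the first-node near-wall speed equal ``v_max``.

    Uses the inlet-section height snapped to the grid, and the plane-
    Poiseuille profile u(y) = 4 U y (H - y) / H^2.
    """
    h_floor = geom.floor_height(0.0)
    H = _snap(geom.height, p.delta) - _snap(h_floor, p.delta)
    d = p.delta
    return p.v_max * H * H / (4.0 * d * (H - d))


def _snap(x: float, delta: float) -> float:
    return round(x / delta) * delta


def _build_mask(geom: ChannelGeometry, delta: float) -> np.ndarray:
    """Rasterise the geometry: True = solid node (walls, ridges, step shelf)."""
    nx = int(round(geom.length / delta)) + 1
    ny = int(round(geom.height / delta)) + 1
    solid = np.zeros((nx, ny), dtype=bool)
    x = np.arange(nx) * delta
    floor = np.array([geom.floor_height(xi) for xi in x])
    y = np.arange(ny) * delta
    solid |= y[None, :] <= floor[:, None] + 1e-12
    solid[:, -1] = True  # top wall
    return solid


def _poiseuille_profile(y: np.ndarray, y0: float, y1: float, u_peak: float) -> np.ndarray:
    h = y1 - y0
    u = 4.0 * u_peak * (y - y0) * (y1 - y) / (h * h)
    u[(y <= y0) | (y >= y1)] = 0.0
    return u


def solve_channel_flow(geom: ChannelGeometry, p: ModelParams,
                       u_peak: float | None = None,
                       u_lattice: float = 0.04,
                       tol: float = 1e-7, check_every: int = 100,
                       max_steps: int = 400_000,
                       force_lb: bool = False,
                       warm_start: bool = True) -> FlowField:
    """Steady incompressible flow through the channel.

    Flat channels return the analytic plane-Poiseuille profile evaluated on
    the grid.  Ridged and backward-step channels run the D2Q9 BGK
    lattice-Boltzmann solver (parabolic velocity inlet, zero-gradient
    outlet, halfway bounce-back) until the maximum relative velocity change
    over ``check_every`` steps falls below ``tol``.

    ``u_lattice`` fixes the peak lattice velocity (low-Mach regime); the
    relaxation time follows from the Reynolds number at the given grid.
    """
    if u_peak is None:
        u_peak = default_peak_speed(geom, p)
    if u_peak <= 0:
        raise ValueError("inflow speed must be positive")
    delta = p.delta
    solid = _build_mask(geom, delta)
    nx, ny = solid.shape
    y = np.arange(ny) * delta
    meta = {"u_peak": u_peak, "geometry_kind": geom.kind}

    if geom.kind == "flat" and not force_lb:
        H = (ny - 1) * delta
        ux = np.tile(_poiseuille_profile(y, 0.0, H, u_peak), (nx, 1))
        ux[solid] = 0.0
        return FlowField(delta, ux, np.zeros_like(ux), solid, meta=meta)

    # lattice-Boltzmann path.  With halfway bounce-back the no-slip plane
    # sits half a link beyond the first fluid node, so profiles are
    # prescribed on the effective wall positions (0.5*delta insets).
    h_in0 = _snap(geom.floor_height(0.0), delta)
    H = (ny - 1) * delta
    inlet_prof = _poiseuille_profile(y, h_in0 + 0.5 * delta, H - 0.5 * delta,
                                     u_peak)
    inlet_prof[solid[0]] = 0.0

    conv = u_lattice / u_peak                    # (lattice u) per (m/s)
    nu_kin = p.nu_dyn / p.rho_fluid              # m^2/s
    delta_m = delta * 1e-3
    nu_lb = nu_kin * u_lattice / (u_peak * delta_m)
    tau = 0.5 + 3.0 * nu_lb
    if tau < 0.505:
        raise ValueError(f"lattice relaxation time {tau:.4f} too close to 0.5; "
                         "raise u_lattice or coarsen the grid")
    omega = 1.0 / tau
    meta.update(tau=tau, nu_lb=nu_lb, u_lattice=u_lattice,
                reynolds=u_peak * (H * 1e-3) / nu_kin)

    # initial guess: a converged coarse-grid (2*delta) solution when warm
    # starting (same fixed point, reached in far fewer fine-grid sweeps),
    # else a local parabolic profile with flux matched across the expansion
    u_init = np.zeros((nx, ny))
    uy_init = np.zeros((nx, ny))
    x = np.arange(nx) * delta
    if warm_start:
        coarse = solve_channel_flow(
            geom, p.with_overrides(delta=2 * delta), u_peak=u_peak,
            u_lattice=u_lattice, tol=max(100 * tol, 1e-6),
            check_every=check_every,
            max_steps=max_steps, force_lb=True, warm_start=False)
        pts = np.column_stack([np.repeat(x, ny),
                               np.tile(y, nx),
                               np.zeros(nx * ny)])
        v = coarse.sample(pts, strict=False)
        u_init = v[:, 0].reshape(nx, ny)
        uy_init = v[:, 1].reshape(nx, ny)
    else:
        for i in range(nx):
            y0 = _snap(geom.floor_height(x[i]), delta)
            h_loc = H - y0 - delta
            u_loc = u_peak * (H - h_in0 - delta) / h_loc
            u_init[i] = _poiseuille_profile(y, y0 + 0.5 * delta, H - 0.5 * delta,
                                            u_loc)
    u_init[solid] = 0.0
    uy_init[solid] = 0.0

    from ._lb import run_lb

    ux_lb, uy_lb, steps, residual = run_lb(
        solid, inlet_prof * conv, u_init * conv, uy_init * conv, omega, tol,
        check_every, max_steps)
    if residual >= tol:
        raise RuntimeError(
            f"lattice-Boltzmann solve did not converge: residual {residual:.3e} "
            f"after {steps} steps (tol {tol:.1e})")
    meta.update(lb_steps=steps, lb_residual=residual)
    ux = ux_lb / conv
    uy = uy_lb / conv
    ux[solid] = 0.0
    uy[solid] = 0.0
    return FlowField(delta, ux, uy, solid, meta=meta)


def sample_velocity(field: FlowField, pos) -> np.ndarray:
    """Velocity vector (m/s) at a position (mm); raises outside the domain."""
    return field.sample(pos, strict=True)


def wall_shear_stress(field: FlowField, p: ModelParams) -> WSSField:
    """First-node WSS along the bottom wall: ``nu_dyn * |u_tangential| / delta``.

    ``delta`` is the lattice spacing converted to metres, exactly the
    near-wall finite-difference rule that makes a 0.036 m/s first-node
    speed correspond to 2.4 Pa.
    """
    x, u = field.near_wall_ux()
    wss = p.nu_dyn * np.abs(u) / (p.delta * 1e-3)
    return WSSField(x=x, wss=wss)


def recirculation_zones(field: FlowField, threshold_frac: float = 1e-6) -> list:
    """Maximal x-intervals of reversed near-wall flow along the bottom wall.

    A node counts as reversed when its near-wall streamwise velocity is
    below ``-threshold_frac * max|u|``.  Interval ends (reattachment points)
    are refined by linear interpolation of the zero crossing.
    """
    x, u = field.near_wall_ux()
    thr = -threshold_frac * np.abs(field.ux).max()
    neg = u < thr
    zones = []
    i = 0
    nx = len(x)
    while i < nx:
        if neg[i]:
            start = i
            while i + 1 < nx and neg[i + 1]:
                i += 1
            end = i
            x0 = x[start]
            if start > 0 and u[start - 1] > u[start]:
                # zero crossing between start-1 and start
                du = u[start] - u[start - 1]
                if du != 0:
                    x0 = x[start - 1] - u[start - 1] / du * field.delta
            x1 = x[end]
            if end + 1 < nx:
                du = u[end + 1] - u[end]
                if du != 0:
                    x1 = x[end] - u[end] / du * field.delta
            zones.append((x0, x1))
        i += 1
    return zones
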
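"""D2Q9 BGK lattice-Boltzmann kernel (numba).

Single-relaxation-time collision, halfway bounce-back on solid links,
velocity (equilibrium) inlet at the first column, pressure-anchored
zero-gradient outlet at the last.  Populations are stored node-major as
``f[i, j, q]`` (contiguous per node) with ``i`` streamwise and ``j``
wall-normal.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# D2Q9 velocity set and weights
_CX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
_CY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
_W = np.array([4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9,
               1 / 36, 1 / 36, 1 / 36, 1 / 36])
_OPP = np.array([0, 3, 4, 1, 2, 7, 8, 5, 6], dtype=np.int64)


@njit(cache=False, fastmath=True)
def _feq_q(q, rho, ux, uy):
    cu = _CX[q] * ux + _CY[q] * uy
    usq = ux * ux + uy * uy
    return _W[q] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)


@njit(cache=False, fastmath=True)
def _collide(f, solid, omega, nx, ny):
    for i in range(nx):
        for j in range(ny):
            if solid[i, j]:
                continue
            rho = 0.0
            mx = 0.0
            my = 0.0
            for q in range(9):
                fq = f[i, j, q]
                rho += fq
                mx += fq * _CX[q]
                my += fq * _CY[q]
            ux = mx / rho
            uy = my / rho
            for q in range(9):
                f[i, j, q] += omega * (_feq_q(q, rho, ux, uy) - f[i, j, q])


@njit(cache=False, fastmath=True)
def _stream(f, fnew, solid, nx, ny):
    # pull streaming with halfway bounce-back on links into solids
    for i in range(nx):
        for j in range(ny):
            if solid[i, j]:
                continue
            for q in range(9):
                si = i - _CX[q]
                sj = j - _CY[q]
                if si < 0 or si >= nx or sj < 0 or sj >= ny or solid[si, sj]:
                    fnew[i, j, q] = f[i, j, _OPP[q]]
                else:
                    fnew[i, j, q] = f[si, sj, q]


@njit(cache=False, fastmath=True)
def _apply_inlet_outlet(f, solid, inlet_ux, nx, ny):
    # inlet: equilibrium at the prescribed profile, density extrapolated
    for j in range(ny):
        if solid[0, j]:
            continue
        rho = 0.0
        for q in range(9):
            rho += f[1, j, q]
        for q in range(9):
            f[0, j, q] = _feq_q(q, rho, inlet_ux[j], 0.0)
    # outlet: zero velocity gradient with the density anchored at 1
    # (a free outflow that also pins the absolute pressure level; a plain
    # population copy lets the domain mass drift indefinitely)
    for j in range(ny):
        if solid[nx - 1, j]:
            continue
        rho = 0.0
        mx = 0.0
        my = 0.0
        for q in range(9):
            fq = f[nx - 2, j, q]
            rho += fq
            mx += fq * _CX[q]
            my += fq * _CY[q]
        for q in range(9):
            f[nx - 1, j, q] = _feq_q(q, 1.0, mx / rho, my / rho)


@njit(cache=False, fastmath=True)
def _macro(f, solid, nx, ny, ux, uy):
    for i in range(nx):
        for j in range(ny):
            if solid[i, j]:
                ux[i, j] = 0.0
                uy[i, j] = 0.0
            else:
                rho = 0.0
                mx = 0.0
                my = 0.0
                for q in range(9):
                    fq = f[i, j, q]
                    rho += fq
                    mx += fq * _CX[q]
                    my += fq * _CY[q]
                ux[i, j] = mx / rho
                uy[i, j] = my / rho


@njit(cache=False, fastmath=True)
def run_lb(solid, inlet_ux, u_init_x, u_init_y, omega, tol, check_every,
           max_steps):
    """Iterate to steady state.

    Returns (ux, uy, n_steps, residual).  ``residual`` is the max velocity
    change over the last ``check_every`` steps relative to the max speed;
    convergence when residual < tol.
    """
    nx, ny = solid.shape
    f = np.empty((nx, ny, 9))
    fnew = np.empty((nx, ny, 9))
    for i in range(nx):
        for j in range(ny):
            for q in range(9):
                f[i, j, q] = _feq_q(q, 1.0, u_init_x[i, j], u_init_y[i, j])

    ux = np.zeros((nx, ny))
    uy = np.zeros((nx, ny))
    ux_prev = np.zeros((nx, ny))
    uy_prev = np.zeros((nx, ny))
    _macro(f, solid, nx, ny, ux_prev, uy_prev)

    residual = 1.0
    step = 0
    while step < max_steps:
        _collide(f, solid, omega, nx, ny)
        _stream(f, fnew, solid, nx, ny)
        tmp = f
        f = fnew
        fnew = tmp
        _apply_inlet_outlet(f, solid, inlet_ux, nx, ny)
        step += 1
        if step % check_every == 0:
            _macro(f, solid, nx, ny, ux, uy)
            umax = 1e-300
            dmax = 0.0
            for i in range(nx):
                for j in range(ny):
                    s = abs(ux[i, j]) + abs(uy[i, j])
                    if s > umax:
                        umax = s
                    d = abs(ux[i, j] - ux_prev[i, j]) + abs(uy[i, j] - uy_prev[i, j])
                    if d > dmax:
                        dmax = d
            residual = dmax / umax
            if residual < tol:
                return ux, uy, step, residual
            ux_prev[:, :] = ux
            uy_prev[:, :] = uy
    _macro(f, solid, nx, ny, ux, uy)
    return ux, uy, step, residual
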
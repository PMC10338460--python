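"""Finite-difference method-of-lines reference for inert-tracer transport.

A deliberately independent discretization of the column model used only to
validate the orthogonal-collocation solver: second-order central differences
on fine uniform axial/radial grids, ghost-node boundary conditions, and an
adaptive stiff ODE integrator. Restricted to non-binding components, for
which the semi-discrete system is linear and the exact Jacobian is the
constant system matrix.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .grm import interstitial_velocity
from .params import ColumnParameters

__all__ = ["fd_system", "fd_breakthrough"]


def fd_system(params: ColumnParameters, comp: int, F_in: float,
              nz: int = 300, nr: int = 20):
    """Sparse system dy/dt = A y + b * c_inj for one inert component.

    State layout: [c_0..c_nz, cp_(z=0,r=0..nr), cp_(z=1,...), ...].
    """
    if params.k_a[comp] != 0 or params.k_d[comp] != 0:
        raise ValueError("finite-difference reference covers inert components only")
    u = interstitial_velocity(F_in, params)
    D_ax = params.D_ax[comp]
    D_p = params.D_p[comp]
    k_f = params.k_f[comp]
    eps_c, eps_p, r_p, L = params.eps_c, params.eps_p, params.r_p, params.L
    dz = L / nz
    dr = r_p / nr
    k_film = (1 - eps_c) / eps_c * 3.0 * k_f / r_p

    n_c = nz + 1
    n_r = nr + 1
    n = n_c + n_c * n_r
    rows, cols, vals = [], [], []
    b = np.zeros(n)

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    def cp_idx(j, m):
        return n_c + j * n_r + m

    for j in range(n_c):
        surf = cp_idx(j, nr)
        if j == 0:
            # Danckwerts inlet via ghost-node elimination
            add(0, 1, 2 * D_ax / dz**2)
            add(0, 0, -2 * D_ax / dz**2 - 2 * u / dz - u**2 / D_ax - k_film)
            b[0] = 2 * u / dz + u**2 / D_ax
            add(0, surf, k_film)
        elif j == nz:
            # zero-gradient outlet via ghost node
            add(j, j - 1, 2 * D_ax / dz**2)
            add(j, j, -2 * D_ax / dz**2 - k_film)
            add(j, surf, k_film)
        else:
            add(j, j - 1, u / (2 * dz) + D_ax / dz**2)
            add(j, j, -2 * D_ax / dz**2 - k_film)
            add(j, j + 1, -u / (2 * dz) + D_ax / dz**2)
            add(j, surf, k_film)
        # pore phase at this axial node
        for m in range(n_r):
            i = cp_idx(j, m)
            if m == 0:
                # symmetry: (c'' + 2/r c') -> 3 c''(0)
                add(i, cp_idx(j, 1), 6 * D_p / dr**2)
                add(i, i, -6 * D_p / dr**2)
            elif m == nr:
                # film-flux surface condition via ghost node
                coeff = 2 * k_f / eps_p * (1.0 / dr + 1.0 / r_p)
                add(i, cp_idx(j, nr - 1), 2 * D_p / dr**2)
                add(i, i, -2 * D_p / dr**2 - coeff)
                add(i, j, coeff)
            else:
                r_m = m * dr
                add(i, cp_idx(j, m - 1), D_p * (1.0 / dr**2 - 1.0 / (r_m * dr)))
                add(i, i, -2 * D_p / dr**2)
                add(i, cp_idx(j, m + 1), D_p * (1.0 / dr**2 + 1.0 / (r_m * dr)))

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return A, b


def fd_breakthrough(params: ColumnParameters, comp: int, F_in: float,
                    c_inj: float, t_eval: np.ndarray, nz: int = 300,
                    nr: int = 20, rtol: float = 1e-8,
                    atol_scale: float = 1e-12) -> np.ndarray:
    """Outlet concentration history of a step inlet of an inert tracer."""
    A, b = fd_system(params, comp, F_in, nz=nz, nr=nr)
    forcing = b * c_inj

    def rhs(_t, y):
        return A @ y + forcing

    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), np.zeros(A.shape[0]),
                    t_eval=t_eval, method="BDF", jac=A, rtol=rtol,
                    atol=atol_scale * max(abs(c_inj), 1.0))
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    nz_nodes = nz + 1
    return sol.y[nz_nodes - 1]
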
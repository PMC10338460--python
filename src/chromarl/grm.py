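"""General rate model of a single chromatography column.

The column couples, per component ``i``:

* interstitial mobile phase  dc/dt = -u dc/dz + D_ax d2c/dz2
  - (1-eps_c)/eps_c * 3 k_f/r_p * (c - c_p(r=r_p))
* pore phase                 dc_p/dt = D_p (d2c_p/dr2 + 2/r dc_p/dr)
  - (1-eps_p)/eps_p * dq/dt
* solid phase (mobile-phase-modulator Langmuir)
  dq/dt = k_a exp(gamma c_p,salt) c_p (q_max - q) - k_d c_p,salt^beta q

with a Danckwerts inlet condition, zero-gradient outlet, film-flux particle
surface condition and symmetry at the particle centre. Space is discretized
by orthogonal collocation on finite elements (C1-continuous interfaces), and
time by backward Euler: the constant-coefficient part of the semi-discrete
system, including the low-loading linearisation ``k_a q_max c_p`` of the
adsorption term, lives in one sparse matrix that is LU-factorised and reused;
the small bilinear binding remainder is resolved by fixed-point iteration
with a Newton fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

from .collocation import CollocationGrid, ConfigurationError, build_collocation_grid
from .params import COMPONENTS, MAB, N_COMP, SALT, ColumnParameters

__all__ = [
    "ColumnState", "ColumnSimulator", "binding_rate", "outlet_concentration",
    "column_mass", "interstitial_velocity", "ConvergenceError",
    "NegativeConcentrationError", "build_column_grid",
]


class ConvergenceError(RuntimeError):
    """Implicit solve failed to converge; carries the last residual norm."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


class NegativeConcentrationError(ValueError):
    """A concentration undershoot exceeded the tolerated numerical noise."""


def build_column_grid(params: ColumnParameters) -> CollocationGrid:
    """Collocation grid matching the column's discretization settings."""
    return build_collocation_grid(params.L, params.r_p, params.N_z,
                                  params.N_r, params.N_p)


def interstitial_velocity(F_in: float, params: ColumnParameters) -> float:
    """u = F_in / (A_c eps_c), m/s."""
    return F_in / (params.A_c * params.eps_c)


def binding_rate(c_p_local: np.ndarray, q_local: np.ndarray,
                 params: ColumnParameters) -> np.ndarray:
    """Per-component solid-phase accumulation rate dq/dt (g m^-3 s^-1).

    Accepts arrays shaped ``(n_comp,)`` or ``(n_comp, ...)``; the salt
    (modulator) concentration is taken from component index 0 of
    ``c_p_local``. Inert components (k_a = k_d = 0) return exactly zero.
    """
    c_p = np.asarray(c_p_local, dtype=float)
    q = np.asarray(q_local, dtype=float)
    if c_p.shape[0] != N_COMP or q.shape != c_p.shape:
        raise ValueError(f"expected leading dimension {N_COMP}, got "
                         f"{c_p.shape} / {q.shape}")
    if np.any(c_p < 0) or np.any(q < 0):
        raise ValueError("binding_rate requires non-negative concentrations "
                         "and loadings")
    salt = c_p[SALT]
    shape_pad = (slice(None),) + (None,) * (c_p.ndim - 1)
    k_a = params.k_a[shape_pad]
    k_d = params.k_d[shape_pad]
    q_max = params.q_max[shape_pad]
    ads = k_a * np.exp(params.gamma_mpm * salt) * c_p * (q_max - q)
    des = k_d * np.power(salt, params.beta_mpm) * q
    return ads - des


def langmuir_equilibrium(c: float, salt: float, params: ColumnParameters,
                         comp: int = MAB) -> float:
    """Closed-form equilibrium loading q* of the modulator-Langmuir isotherm.

    Root of the kinetic rate at fixed pore concentration ``c`` and salt
    level ``salt``.
    """
    k_a = params.k_a[comp] * np.exp(params.gamma_mpm * salt)
    k_d = params.k_d[comp] * salt ** params.beta_mpm
    denom = k_a * c + k_d
    if denom == 0.0:
        return 0.0
    return params.q_max[comp] * k_a * c / denom


@dataclass
class ColumnState:
    """All column unknowns at one time point.

    ``c``  : (n_comp, n_axial) interstitial concentrations, g/m^3
    ``cp`` : (n_comp, n_axial, n_radial) pore concentrations
    ``q``  : (n_comp, n_axial, n_radial) solid loadings
    """

    t: float
    c: np.ndarray
    cp: np.ndarray
    q: np.ndarray

    @classmethod
    def zeros(cls, grid: CollocationGrid) -> "ColumnState":
        nz, nr = grid.n_axial, grid.n_radial
        return cls(0.0, np.zeros((N_COMP, nz)), np.zeros((N_COMP, nz, nr)),
                   np.zeros((N_COMP, nz, nr)))

    def copy(self) -> "ColumnState":
        return ColumnState(self.t, self.c.copy(), self.cp.copy(), self.q.copy())

    def to_vector(self) -> np.ndarray:
        """Per-component flat layout: [c | cp(z-major) | q], shape (n_comp, n)."""
        nc, nz, nr = self.cp.shape
        return np.concatenate(
            [self.c, self.cp.reshape(nc, nz * nr), self.q.reshape(nc, nz * nr)],
            axis=1)

    @classmethod
    def from_vector(cls, y: np.ndarray, t: float, nz: int, nr: int) -> "ColumnState":
        nc = y.shape[0]
        c = y[:, :nz].copy()
        cp = y[:, nz:nz + nz * nr].reshape(nc, nz, nr).copy()
        q = y[:, nz + nz * nr:].reshape(nc, nz, nr).copy()
        return cls(t, c, cp, q)

    def check(self, params: ColumnParameters, abs_tol: float = 1e-9,
              rel_tol: float = 0.05,
              scale_hint: np.ndarray | None = None) -> None:
        """Reject concentration undershoots beyond numerical noise.

        Undershoots are never clipped; small ones (below ``abs_tol`` plus
        ``rel_tol`` of the component's natural scale - its current field
        maximum, the driving inlet concentration passed as ``scale_hint``,
        or the binding capacity for the solid phase) are tolerated so
        conservation bookkeeping stays exact, larger ones indicate solver
        failure and raise. Spectral collocation leaves wiggles of a few
        percent of the driving scale at sharp fronts; genuine solver
        failures overshoot by orders of magnitude.
        """
        for name, arr in (("c", self.c), ("cp", self.cp), ("q", self.q)):
            scale = np.abs(arr).max(axis=tuple(range(1, arr.ndim)), initial=0.0)
            if name == "q":
                scale = np.maximum(scale, params.q_max)
            elif scale_hint is not None:
                scale = np.maximum(scale, scale_hint)
            tol = abs_tol + rel_tol * scale
            low = arr.min(axis=tuple(range(1, arr.ndim)), initial=0.0)
            if np.any(low < -tol):
                i = int(np.argmin(low + tol))
                raise NegativeConcentrationError(
                    f"{name}[{COMPONENTS.names[i]}] reached {low[i]:.3e} "
                    f"(tolerance {-tol[i]:.3e})")
        q_cap = (1.0 + rel_tol) * params.q_max[:, None, None] + abs_tol
        binding = params.q_max > 0
        if np.any(self.q[binding] > q_cap[binding]):
            raise NegativeConcentrationError("solid loading exceeded q_max")


def outlet_concentration(state: ColumnState) -> np.ndarray:
    """Mobile-phase concentrations at the last axial node (z = L), g/m^3."""
    return state.c[:, -1].copy()


def column_mass(state: ColumnState, params: ColumnParameters,
                grid: CollocationGrid) -> np.ndarray:
    """Per-component mass held in the column (g).

    Integrates eps_c*c + (1-eps_c)*(eps_p*<c_p> + (1-eps_p)*<q>) over the
    column volume, where <.> is the spherical volume average over the
    particle radius, using quadrature consistent with the collocation grid.
    """
    avg_cp = grid.radial_volume_average(state.cp)   # (n_comp, n_axial)
    avg_q = grid.radial_volume_average(state.q)
    per_z = (params.eps_c * state.c
             + (1 - params.eps_c) * (params.eps_p * avg_cp
                                     + (1 - params.eps_p) * avg_q))
    return params.A_c * (per_z @ grid.axial.quad_weights)


class _ComponentOperator:
    """Constant sparse operators for one component's semi-discrete system.

    System form: M ydot = (A0 + u*A1) y + b(u, t) + n(y), where M is the
    0/1 diagonal marking differential vs algebraic (boundary / C1-interface)
    rows and b carries the inlet forcing u*c_inj on the Danckwerts row.
    """

    def __init__(self, comp: int, params: ColumnParameters, grid: CollocationGrid):
        self.comp = comp
        nz, nr = grid.n_axial, grid.n_radial
        self.nz, self.nr = nz, nr
        self.n = nz + 2 * nz * nr
        off_cp = nz
        off_q = nz + nz * nr
        self.off_cp, self.off_q = off_cp, off_q

        def cp_idx(z, j):
            return off_cp + z * nr + j

        def q_idx(z, j):
            return off_q + z * nr + j

        D_ax = params.D_ax[comp]
        D_p = params.D_p[comp]
        k_f = params.k_f[comp]
        lin_bind = params.k_a[comp] * params.q_max[comp]
        phi_c = (1 - params.eps_c) / params.eps_c
        phi_p = (1 - params.eps_p) / params.eps_p
        k_film = phi_c * 3.0 * k_f / params.r_p
        self.phi_p = phi_p
        # key identifying matrix-identical components (shared factorization)
        self.matrix_key = (D_ax, D_p, k_f, lin_bind)

        ax, rad = grid.axial, grid.radial
        Mdiag = np.ones(self.n)
        r0, c0_, v0 = [], [], []    # constant part A0
        r1, c1_, v1 = [], [], []    # u-scaled part A1

        def add0(row, cols, vals):
            r0.extend([row] * len(cols))
            c0_.extend(cols)
            v0.extend(vals)

        def add1(row, cols, vals):
            r1.extend([row] * len(cols))
            c1_.extend(cols)
            v1.extend(vals)

        # ---- axial mobile phase rows -------------------------------------
        # inlet (Danckwerts, algebraic): 0 = u*c_inj - u*c(0) + D_ax c'(0)
        Mdiag[0] = 0.0
        gi0 = ax.elem_index[0]
        add0(0, list(gi0), list(D_ax * ax.D1_elem[0][0]))
        add1(0, [0], [-1.0])
        # outlet (algebraic): 0 = c'(L)
        Mdiag[nz - 1] = 0.0
        gil = ax.elem_index[-1]
        add0(nz - 1, list(gil), list(ax.D1_elem[-1][-1]))
        # element interfaces (algebraic): C1 continuity
        for e in range(1, ax.n_elements):
            g = e * ax.order
            Mdiag[g] = 0.0
            add0(g, list(ax.elem_index[e - 1]), list(ax.D1_elem[e - 1][-1]))
            add0(g, list(ax.elem_index[e]), list(-ax.D1_elem[e][0]))
        # interior collocation rows
        for e in range(ax.n_elements):
            for li in range(1, ax.order):
                g = ax.elem_index[e][li]
                cols = list(ax.elem_index[e])
                add1(g, cols, list(-ax.D1_elem[e][li]))
                add0(g, cols, list(D_ax * ax.D2_elem[e][li]))
                add0(g, [g, cp_idx(g, nr - 1)], [-k_film, k_film])

        # ---- pore phase rows (independent per axial node) ----------------
        r_nodes = rad.nodes
        for z in range(nz):
            # particle centre symmetry (algebraic): c_p'(0) = 0
            row = cp_idx(z, 0)
            Mdiag[row] = 0.0
            add0(row, [cp_idx(z, j) for j in rad.elem_index[0]],
                 list(rad.D1_elem[0][0]))
            # film flux surface condition (algebraic):
            # 0 = k_f (c - c_p(r_p)) - eps_p D_p c_p'(r_p)
            row = cp_idx(z, nr - 1)
            Mdiag[row] = 0.0
            add0(row, [z, cp_idx(z, nr - 1)], [k_f, -k_f])
            add0(row, [cp_idx(z, j) for j in rad.elem_index[-1]],
                 list(-params.eps_p * D_p * rad.D1_elem[-1][-1]))
            # radial C1 interfaces
            for e in range(1, rad.n_elements):
                j = e * rad.order
                row = cp_idx(z, j)
                Mdiag[row] = 0.0
                add0(row, [cp_idx(z, jj) for jj in rad.elem_index[e - 1]],
                     list(rad.D1_elem[e - 1][-1]))
                add0(row, [cp_idx(z, jj) for jj in rad.elem_index[e]],
                     list(-rad.D1_elem[e][0]))
            # interior pore rows
            for e in range(rad.n_elements):
                for lj in range(1, rad.order):
                    j = rad.elem_index[e][lj]
                    row = cp_idx(z, j)
                    cols = [cp_idx(z, jj) for jj in rad.elem_index[e]]
                    vals = D_p * (rad.D2_elem[e][lj]
                                  + (2.0 / r_nodes[j]) * rad.D1_elem[e][lj])
                    add0(row, cols, list(vals))
                    if lin_bind:
                        add0(row, [cp_idx(z, j)], [-phi_p * lin_bind])
            # solid phase rows: dq/dt = k_a q_max c_p + remainder
            if lin_bind:
                for j in range(nr):
                    add0(q_idx(z, j), [cp_idx(z, j)], [lin_bind])

        n = self.n
        self.Mdiag = Mdiag
        self.A0 = sp.csr_matrix((v0, (r0, c0_)), shape=(n, n))
        self.A1 = sp.csr_matrix((v1, (r1, c1_)), shape=(n, n))
        # mask of differential pore rows receiving the -phi_p dq/dt source
        pore_diff = np.zeros(nz * nr, dtype=bool)
        pore_diff[:] = (Mdiag[off_cp:off_q] > 0)
        self.pore_diff_mask = pore_diff.reshape(nz, nr)

    def system_matrix(self, u: float, h: float) -> sp.csc_matrix:
        """K = M - h (A0 + u A1), the backward-Euler matrix."""
        K = sp.diags(self.Mdiag) - h * (self.A0 + u * self.A1)
        return K.tocsc()


class ColumnSimulator:
    """Backward-Euler integrator for one column's general rate model."""

    def __init__(self, params: ColumnParameters, grid: CollocationGrid | None = None,
                 fp_rtol: float = 1e-10, fp_maxiter: int = 50,
                 newton_maxiter: int = 25, max_factor_cache: int = 128):
        if params.N_p < 2:
            raise ConfigurationError(
                "column simulation needs polynomial order N_p >= 2 "
                "(second derivatives vanish below that)")
        self.params = params
        self.grid = grid if grid is not None else build_column_grid(params)
        self.ops = [_ComponentOperator(i, params, self.grid)
                    for i in range(N_COMP)]
        self.fp_rtol = fp_rtol
        self.fp_maxiter = fp_maxiter
        self.newton_maxiter = newton_maxiter
        self._lu_cache: dict = {}
        self._max_cache = max_factor_cache
        self.nz, self.nr = self.grid.n_axial, self.grid.n_radial
        # running per-component concentration scale (largest inlet or field
        # value seen so far) against which undershoots are judged
        self._scale_hint = np.zeros(N_COMP)

    # -- factorization cache ------------------------------------------------
    def _lu(self, comp: int, u: float, h: float):
        key = (self.ops[comp].matrix_key, u, h)
        lu = self._lu_cache.get(key)
        if lu is None:
            if len(self._lu_cache) >= self._max_cache:
                self._lu_cache.clear()
            lu = splu(self.ops[comp].system_matrix(u, h))
            self._lu_cache[key] = lu
        return lu

    # -- nonlinear binding remainder -----------------------------------------
    def _remainder(self, comp: int, cp_salt: np.ndarray, cp: np.ndarray,
                   q: np.ndarray) -> np.ndarray:
        """Binding rate minus its k_a*q_max*c_p linear part, per (z, r) node."""
        p = self.params
        k_a, k_d, q_max = p.k_a[comp], p.k_d[comp], p.q_max[comp]
        salt = np.clip(cp_salt, 0.0, None)   # guard power/exp against undershoot
        full = (k_a * np.exp(p.gamma_mpm * salt) * cp * (q_max - q)
                - k_d * np.power(salt, p.beta_mpm) * q)
        return full - k_a * q_max * cp

    def _remainder_jacobian(self, comp: int, cp_salt, cp, q):
        """d(remainder)/d(cp), d(remainder)/d(q) per (z, r) node."""
        p = self.params
        k_a, k_d, q_max = p.k_a[comp], p.k_d[comp], p.q_max[comp]
        salt = np.clip(cp_salt, 0.0, None)
        mod = np.exp(p.gamma_mpm * salt)
        d_cp = k_a * (mod * (q_max - q) - q_max)
        d_q = -k_a * mod * cp - k_d * np.power(salt, p.beta_mpm)
        return d_cp, d_q

    def _rhs_const(self, op: _ComponentOperator, y0_i: np.ndarray, u: float,
                   h: float, c_inj: float) -> np.ndarray:
        rhs = op.Mdiag * y0_i
        rhs[0] += h * u * c_inj   # Danckwerts inlet forcing
        return rhs

    def _nonlinear_rhs(self, comp: int, op: _ComponentOperator,
                       cp_salt: np.ndarray, y_i: np.ndarray) -> np.ndarray:
        nz, nr = self.nz, self.nr
        cp = y_i[op.off_cp:op.off_q].reshape(nz, nr)
        q = y_i[op.off_q:].reshape(nz, nr)
        rem = self._remainder(comp, cp_salt, cp, q)
        n_vec = np.zeros(op.n)
        n_vec[op.off_q:] = rem.ravel()
        src = np.where(op.pore_diff_mask, -op.phi_p * rem, 0.0)
        n_vec[op.off_cp:op.off_q] = src.ravel()
        return n_vec

    # -- single implicit step -------------------------------------------------
    def step(self, state: ColumnState, F_in: float,
             inlet_conc: np.ndarray, h: float | None = None,
             n_substeps: int = 1) -> ColumnState:
        """Advance the column by one timestep of length ``h`` (default
        ``params.h``), optionally split into equal implicit substeps.

        ``inlet_conc`` is held constant over the step (piecewise-constant
        control)."""
        if F_in < 0:
            raise ValueError("F_in must be non-negative")
        h = self.params.h if h is None else float(h)
        if h <= 0:
            raise ValueError("step length must be positive")
        inlet_conc = np.asarray(inlet_conc, dtype=float)
        if inlet_conc.shape != (N_COMP,):
            raise ValueError(f"inlet_conc must have shape ({N_COMP},)")
        hs = h / n_substeps
        u = interstitial_velocity(F_in, self.params)
        y = state.to_vector()
        t = state.t
        for _ in range(n_substeps):
            y = self._implicit_substep(y, u, hs, inlet_conc)
            t += hs
        out = ColumnState.from_vector(y, t, self.nz, self.nr)
        self._scale_hint = np.maximum(
            self._scale_hint,
            np.maximum(inlet_conc, np.abs(out.c).max(axis=1)))
        out.check(self.params, scale_hint=self._scale_hint)
        return out

    def _implicit_substep(self, y0: np.ndarray, u: float, h: float,
                          inlet_conc: np.ndarray) -> np.ndarray:
        y1 = np.empty_like(y0)
        # inert components are linear: one solve each (salt first, since the
        # binding remainder of the protein needs the new salt pore field)
        binding = [i for i in range(N_COMP)
                   if self.params.k_a[i] > 0 or self.params.k_d[i] > 0]
        for i in range(N_COMP):
            if i in binding:
                continue
            op = self.ops[i]
            rhs = self._rhs_const(op, y0[i], u, h, inlet_conc[i])
            y1[i] = self._lu(i, u, h).solve(rhs)
        op_s = self.ops[SALT]
        cp_salt = y1[SALT][op_s.off_cp:op_s.off_q].reshape(self.nz, self.nr)

        for i in binding:
            op = self.ops[i]
            lu = self._lu(i, u, h)
            rhs0 = self._rhs_const(op, y0[i], u, h, inlet_conc[i])
            yi = y0[i]
            converged = False
            prev_dy = np.inf
            grew = 0
            for _ in range(self.fp_maxiter):
                n_vec = self._nonlinear_rhs(i, op, cp_salt, yi)
                yi_new = lu.solve(rhs0 + h * n_vec)
                dy = np.linalg.norm(yi_new - yi)
                yi = yi_new
                if not np.isfinite(dy):
                    grew = 99
                    break
                if dy <= self.fp_rtol * np.linalg.norm(yi) + 1e-300:
                    converged = True
                    break
                grew = grew + 1 if dy > prev_dy else 0
                if grew >= 2:   # diverging: hand over to Newton immediately
                    break
                prev_dy = dy
            if not converged:
                yi = self._newton_substep(i, op, y0[i], rhs0, cp_salt, u, h,
                                          y0[i])
            y1[i] = yi
        return y1

    def _newton_substep(self, comp, op, y0_i, rhs0, cp_salt, u, h, y_init):
        """Newton fallback on K y - rhs0 - h n(y) = 0 for stiff binding."""
        K = op.system_matrix(u, h)
        yi = y_init.copy()
        nz, nr = self.nz, self.nr
        res_norm = np.inf
        for _ in range(self.newton_maxiter):
            n_vec = self._nonlinear_rhs(comp, op, cp_salt, yi)
            res = K @ yi - rhs0 - h * n_vec
            res_norm = np.linalg.norm(res)
            if res_norm <= self.fp_rtol * (np.linalg.norm(yi) + 1.0):
                return yi
            cp = yi[op.off_cp:op.off_q].reshape(nz, nr)
            q = yi[op.off_q:].reshape(nz, nr)
            d_cp, d_q = self._remainder_jacobian(comp, cp_salt, cp, q)
            pore = op.pore_diff_mask.ravel()
            idx_cp = op.off_cp + np.arange(nz * nr)
            idx_q = op.off_q + np.arange(nz * nr)
            rows = np.concatenate([idx_q, idx_q,
                                   idx_cp[pore], idx_cp[pore]])
            cols = np.concatenate([idx_cp, idx_q,
                                   idx_cp[pore], idx_q[pore]])
            vals = np.concatenate([
                d_cp.ravel(), d_q.ravel(),
                -op.phi_p * d_cp.ravel()[pore], -op.phi_p * d_q.ravel()[pore]])
            Jn = sp.csc_matrix((vals, (rows, cols)), shape=(op.n, op.n))
            delta = splu((K - h * Jn).tocsc()).solve(-res)
            yi = yi + delta
        raise ConvergenceError(
            f"implicit binding solve for component "
            f"'{COMPONENTS.names[comp]}' did not converge", res_norm)

    # -- explicit right-hand side (diagnostics / oracle comparisons) ---------
    def rhs(self, state: ColumnState, F_in: float, inlet_conc: np.ndarray,
            inlet_rate: np.ndarray | None = None) -> ColumnState:
        """Time derivative of every column unknown at ``state``.

        Differential rows evaluate the semi-discrete operator directly; the
        algebraic boundary / interface constraints are differentiated in time
        (index reduction), so a state satisfying the constraints keeps
        satisfying them. ``inlet_rate`` is d(c_inj)/dt (default zero:
        piecewise-constant control).
        """
        u = interstitial_velocity(F_in, self.params)
        inlet_conc = np.asarray(inlet_conc, dtype=float)
        if inlet_rate is None:
            inlet_rate = np.zeros(N_COMP)
        y = state.to_vector()
        ydot = np.zeros_like(y)
        op_s = self.ops[SALT]
        cp_salt = y[SALT][op_s.off_cp:op_s.off_q].reshape(self.nz, self.nr)
        for i in range(N_COMP):
            op = self.ops[i]
            A = op.A0 + u * op.A1
            f = A @ y[i]
            f[0] += u * inlet_conc[i]
            f += self._nonlinear_rhs(i, op, cp_salt, y[i])
            diff = op.Mdiag > 0
            ydot[i, diff] = f[diff]
            # algebraic rows satisfy 0 = (A y)_row + b_row at all times, so
            # (A ydot)_row = -bdot_row; solve for the constrained unknowns
            alg = ~diff
            if np.any(alg):
                bdot = np.zeros(op.n)
                bdot[0] = u * inlet_rate[i]
                G = A[alg].tocsc()
                rhs_c = -bdot[alg] - G[:, diff] @ ydot[i, diff]
                ydot[i, alg] = spsolve(G[:, alg], rhs_c)
        return ColumnState.from_vector(ydot, state.t, self.nz, self.nr)

    def residual(self, y0: ColumnState, y1: ColumnState, F_in: float,
                 inlet_conc: np.ndarray, h: float) -> float:
        """Backward-Euler defect  || M (y1 - y0) - h M f(y1) ||  over the
        differential rows (the defining equation of the implicit step)."""
        v0, v1 = y0.to_vector(), y1.to_vector()
        u = interstitial_velocity(F_in, self.params)
        op_s = self.ops[SALT]
        cp_salt = v1[SALT][op_s.off_cp:op_s.off_q].reshape(self.nz, self.nr)
        total = 0.0
        for i in range(N_COMP):
            op = self.ops[i]
            f = (op.A0 + u * op.A1) @ v1[i]
            f[0] += u * inlet_conc[i]
            f += self._nonlinear_rhs(i, op, cp_salt, v1[i])
            diff = op.Mdiag > 0
            res = (v1[i] - v0[i]) - h * f
            total += float(np.sum(res[diff] ** 2))
        return np.sqrt(total)
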
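import numpy as np
import pytest
from scipy.integrate import solve_ivp

from chromarl.grm import (ColumnSimulator, ColumnState,
                          NegativeConcentrationError, binding_rate,
                          build_column_grid, column_mass, interstitial_velocity,
                          langmuir_equilibrium, outlet_concentration)
from chromarl.params import MAB, SALT, SM, WASH, ColumnParameters
from chromarl.collocation import ConfigurationError

FEED = np.array([1e-7, 1e-8, 1e-7, 0.0])   # salt, mab, sm, wash


# ---------------------------------------------------------------------------
# binding kinetics
# ---------------------------------------------------------------------------

class TestBindingRate:
    def test_salt_and_wash_are_inert(self, nominal_params):
        cp = np.array([3.0, 0.5, 0.2, 0.9])
        q = np.array([0.0, 0.4, 0.0, 0.0])
        rate = binding_rate(cp, q, nominal_params)
        assert rate[SALT] == 0.0
        assert rate[WASH] == 0.0
        assert rate[SM] == 0.0

    def test_saturated_without_modulator_is_zero(self, nominal_params):
        cp = np.zeros(4)
        cp[MAB] = 0.5
        q = np.zeros(4)
        q[MAB] = nominal_params.q_max[MAB]   # saturated sites, no salt
        assert binding_rate(cp, q, nominal_params)[MAB] == 0.0

    def test_hand_evaluated_adsorption_rate(self, nominal_params):
        # k_a=1, q_max=1, gamma=0: rate = 1 * exp(0) * 0.1 * (1 - 0) = 0.1
        cp = np.zeros(4)
        cp[MAB] = 0.1
        rate = binding_rate(cp, np.zeros(4), nominal_params)
        assert rate[MAB] == pytest.approx(0.1, rel=1e-14)

    @pytest.mark.parametrize("c,salt", [(1e-8, 1e-7), (0.5, 2.0), (3.0, 0.1)])
    def test_equilibrium_loading_is_kinetic_root(self, nominal_params, c, salt):
        q_star = langmuir_equilibrium(c, salt, nominal_params)
        cp = np.zeros(4)
        cp[SALT], cp[MAB] = salt, c
        q = np.zeros(4)
        q[MAB] = q_star
        # rate at q* vanishes up to roundoff of the adsorption term
        ads_scale = nominal_params.k_a[MAB] * c
        assert abs(binding_rate(cp, q, nominal_params)[MAB]) < 1e-14 * max(ads_scale, 1e-10)

    def test_equilibrium_monotone_in_protein_decreasing_in_salt(self, nominal_params):
        qs = [langmuir_equilibrium(c, 1.0, nominal_params) for c in (0.1, 0.5, 2.0)]
        assert qs == sorted(qs)
        qsalt = [langmuir_equilibrium(0.5, s, nominal_params) for s in (0.5, 1.0, 5.0)]
        assert qsalt == sorted(qsalt, reverse=True)

    def test_negative_inputs_rejected(self, nominal_params):
        bad = np.zeros(4)
        bad[MAB] = -1e-3
        with pytest.raises(ValueError):
            binding_rate(bad, np.zeros(4), nominal_params)


def test_isotherm_relaxation_matches_closed_form(nominal_params):
    """Integrating dq/dt at fixed pore concentration converges to the
    closed-form equilibrium loading."""
    c, salt = 0.05, 2.0
    cp = np.zeros(4)
    cp[SALT], cp[MAB] = salt, c

    def rhs(_t, q):
        qv = np.zeros(4)
        qv[MAB] = q[0]
        return [binding_rate(cp, qv, nominal_params)[MAB]]

    q_star = langmuir_equilibrium(c, salt, nominal_params)
    sol = solve_ivp(rhs, (0, 2000.0), [0.0], rtol=1e-12, atol=1e-16)
    assert sol.y[0, -1] == pytest.approx(q_star, rel=1e-6)


# ---------------------------------------------------------------------------
# implicit stepping
# ---------------------------------------------------------------------------

class TestStepping:
    def test_stationary_empty_column(self, small_params):
        sim = ColumnSimulator(small_params)
        st = ColumnState.zeros(sim.grid)
        out = sim.step(st, 0.0, np.zeros(4))
        assert np.all(out.c == 0) and np.all(out.cp == 0) and np.all(out.q == 0)
        assert out.t == small_params.h

    def test_backward_euler_defect_is_small(self, small_params):
        """The returned state satisfies the defining implicit equation."""
        sim = ColumnSimulator(small_params)
        st = ColumnState.zeros(sim.grid)
        for _ in range(5):
            st = sim.step(st, 2e-6, FEED)
        nxt = sim.step(st, 2e-6, FEED)
        res = sim.residual(st, nxt, 2e-6, FEED, small_params.h)
        norm = np.linalg.norm(st.to_vector())
        assert res < 1e-8 * norm

    def test_rhs_zero_state_zero_inlet(self, small_params):
        sim = ColumnSimulator(small_params)
        st = ColumnState.zeros(sim.grid)
        dot = sim.rhs(st, 2e-6, np.zeros(4))
        assert np.allclose(dot.to_vector(), 0.0, atol=1e-30)

    def test_polynomial_order_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            ColumnSimulator(ColumnParameters(N_p=1))

    def test_large_undershoot_raises(self, small_params):
        sim = ColumnSimulator(small_params)
        st = ColumnState.zeros(sim.grid)
        st.c[SM, 3] = -1.0
        with pytest.raises(NegativeConcentrationError):
            st.check(small_params)


def test_plug_flow_breakthrough_time():
    """With film transfer switched off and small dispersion, the mean
    breakthrough time of a step input approaches L/u."""
    p = ColumnParameters(D_ax=5e-5, k_f=0.0, N_z=8, N_r=1, N_p=4, h=0.25)
    F = 2e-7
    u = interstitial_velocity(F, p)
    sim = ColumnSimulator(p)
    st = ColumnState.zeros(sim.grid)
    cin = np.zeros(4)
    cin[SM] = 1.0
    t_end = 4 * p.L / u
    times, outs = [], []
    for _ in range(int(t_end / p.h)):
        st = sim.step(st, F, cin)
        times.append(st.t)
        outs.append(outlet_concentration(st)[SM])
    times, outs = np.array(times), np.array(outs)
    # first temporal moment of d(c_out)/dt
    dc = np.diff(outs, prepend=0.0)
    t_mean = float(np.sum(times * dc) / np.sum(dc))
    assert t_mean == pytest.approx(p.L / u, rel=0.05)


def test_outlet_long_loading_saturates_to_inlet(small_params):
    sim = ColumnSimulator(small_params)
    st = ColumnState.zeros(sim.grid)
    for _ in range(80):
        st = sim.step(st, 2e-6, FEED)
    out = outlet_concentration(st)
    # inert components saturate to the inlet level
    assert out[SALT] == pytest.approx(FEED[SALT], rel=1e-6)
    assert out[SM] == pytest.approx(FEED[SM], rel=1e-6)


def test_inert_components_never_accumulate_on_solid(small_params):
    sim = ColumnSimulator(small_params)
    st = ColumnState.zeros(sim.grid)
    for _ in range(20):
        st = sim.step(st, 1.5e-6, FEED)
    for comp in (SALT, SM, WASH):
        assert np.all(st.q[comp] == 0.0)


# ---------------------------------------------------------------------------
# mass bookkeeping
# ---------------------------------------------------------------------------

class TestColumnMass:
    def test_zero_state(self, small_params):
        sim = ColumnSimulator(small_params)
        st = ColumnState.zeros(sim.grid)
        assert np.all(column_mass(st, small_params, sim.grid) == 0.0)

    def test_uniform_unit_concentrations(self, small_params):
        p = small_params
        sim = ColumnSimulator(p)
        st = ColumnState.zeros(sim.grid)
        st.c[:] = 1.0
        st.cp[:] = 1.0
        expected = p.A_c * p.L * (p.eps_c + (1 - p.eps_c) * p.eps_p)
        m = column_mass(st, p, sim.grid)
        assert np.allclose(m, expected, rtol=1e-10)

    def test_smooth_field_matches_dense_trapezoid_quadrature(self, small_params):
        """Collocation quadrature agrees with an independent dense
        trapezoidal integration on an analytically evaluable smooth field."""
        p = small_params
        sim = ColumnSimulator(p)
        grid = sim.grid
        z = grid.axial.nodes
        r = grid.radial.nodes

        fz = lambda z_: 1.0 + np.sin(2 * np.pi * z_ / p.L)          # noqa: E731
        fr = lambda r_: 1.0 + (r_ / p.r_p) ** 2                      # noqa: E731
        st = ColumnState.zeros(grid)
        st.c[:] = fz(z)
        st.cp[:] = fz(z)[None, :, None] * fr(r)[None, None, :]
        m = column_mass(st, p, grid)

        zz = np.linspace(0, p.L, 4001)
        rr = np.linspace(0, p.r_p, 4001)
        avg_cp = np.trapezoid(fr(rr) * rr**2, rr) * 3 / p.r_p**3
        per_z = (p.eps_c * fz(zz)
                 + (1 - p.eps_c) * p.eps_p * fz(zz) * avg_cp)
        expected = p.A_c * np.trapezoid(per_z, zz)
        assert m[SALT] == pytest.approx(expected, rel=1e-3)


def test_global_mass_conservation_under_varying_flow(small_params):
    """Inlet minus outlet equals the column inventory change per component,
    across flow changes and valve-free accounting."""
    sim = ColumnSimulator(small_params)
    st = ColumnState.zeros(sim.grid)
    fed = np.zeros(4)
    out = np.zeros(4)
    h = small_params.h
    rng = np.random.default_rng(7)
    for k in range(60):
        F = float(rng.uniform(0, 2e-6))
        cin = FEED if k < 40 else np.array([10.0, 0.0, 0.0, 0.0])
        st = sim.step(st, F, cin)
        fed += F * cin * h
        out += F * outlet_concentration(st) * h
    held = column_mass(st, small_params, sim.grid)
    imbalance = fed - out - held
    throughput = np.maximum(fed, 1e-300)
    assert np.all(np.abs(imbalance) / throughput < 5e-3)


def test_grid_self_convergence():
    """Doubling the axial element count changes the outlet curve by a
    decreasing amount."""
    outs = {}
    F, c0 = 2e-7, 1.0
    for nz in (4, 8, 16):
        p = ColumnParameters(D_ax=1e-4, N_z=nz, N_r=2, N_p=3, h=1.0)
        sim = ColumnSimulator(p)
        st = ColumnState.zeros(sim.grid)
        cin = np.zeros(4)
        cin[SM] = c0
        curve = []
        for _ in range(90):
            st = sim.step(st, F, cin)
            curve.append(outlet_concentration(st)[SM])
        outs[nz] = np.array(curve)
    d1 = np.linalg.norm(outs[8] - outs[4])
    d2 = np.linalg.norm(outs[16] - outs[8])
    assert d2 < d1
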
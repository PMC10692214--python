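"""Hemodynamic solver physics: friction closure, velocity profile, the
steady Hagen-Poiseuille oracle, equilibrium states, mass conservation,
valve rectification and grid convergence."""

import numpy as np
import pytest

from lymphchain.activation import ActivationField
from lymphchain.solver import (
    ChainGeometry,
    ChainSolver,
    DegenerateLumenError,
    FluidParams,
    check_mass_conservation,
    friction_term,
    velocity_profile,
)
from lymphchain.valve import ValveParams
from lymphchain.wall import ConstitutiveCurve, ConstitutiveCurveSet, calibrate_default_curves


def flat_field(geometry, period, dt, level=0.0):
    """Spatially/temporally constant activation field on the solver grid."""
    n = int(round(period / dt))
    t = np.arange(n) * dt
    values = np.full((geometry.n_nodes, n), float(level))
    values.flat[0] = max(level, 1.0)  # keep the normalization invariant
    if level == 0.0:
        values.flat[0] = 1.0
        values[:, :] = 0.0
        values[0, 0] = 1e-300  # effectively zero drive
    return ActivationField(z_grid=geometry.node_z, t_grid=t, values=values,
                           gamma=1.0, period_T=period)


def rigid_curves(d_um=255.0):
    """Nearly rigid wall: vanishing slope so C ~ 0 and d is pressure-free."""
    eps = 1e-9
    pre = ConstitutiveCurve(d_max=(d_um + eps) * 1e-4, d_min=d_um * 1e-4, k=1e-6)
    peak = ConstitutiveCurve(d_max=(0.4 * d_um + eps) * 1e-4,
                             d_min=0.4 * d_um * 1e-4, k=1e-6)
    return ConstitutiveCurveSet(pre=pre, peak=peak)


def transparent_valves(rv=1.0):
    return ValveParams(rv_min=rv, rv_max=1e-6, s_o=1.0, p_o=-0.1, s_f=1.0,
                       p_f=-50.0)


class TestFriction:
    def test_zero_flow_no_friction(self):
        assert friction_term(0.0, 1e-4, FluidParams()) == 0.0

    def test_poiseuille_reduction_for_zeta_2(self):
        """tau = -8 mu pi Q/A; the steady momentum balance then gives the
        Hagen-Poiseuille pressure gradient 128 mu Q / (pi d^4)."""
        fl = FluidParams()
        Q, d = 1e-5, 0.02
        A = np.pi * d * d / 4
        tau = friction_term(Q, A, fl)
        assert tau == pytest.approx(-8 * fl.mu * np.pi * Q / A)
        dpdz = tau / A
        assert dpdz == pytest.approx(-128 * fl.mu * Q / (np.pi * d**4))

    def test_friction_opposes_flow(self):
        fl = FluidParams()
        for q in (-1e-4, -1e-7, 1e-7, 1e-4):
            assert friction_term(q, 1e-4, fl) * q <= 0

    def test_collapsed_lumen_rejected(self):
        with pytest.raises(DegenerateLumenError):
            friction_term(1e-5, 0.0, FluidParams())


class TestVelocityProfile:
    def test_centreline_peak_and_no_slip(self):
        A = np.pi * 0.02**2 / 4
        r_i = np.sqrt(A / np.pi)
        u0 = velocity_profile(0.0, 1e-5, A, zeta=2.0)
        assert u0 == pytest.approx(2.0 * 1e-5 / A)
        assert velocity_profile(r_i, 1e-5, A, zeta=2.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("zeta", [2.0, 4.0, 9.0])
    def test_cross_section_average_is_mean_velocity(self, zeta):
        """Quadrature of u(r) 2 pi r dr over the lumen must return Q."""
        from scipy.integrate import quad

        A = np.pi * 0.02**2 / 4
        r_i = np.sqrt(A / np.pi)
        Q = 2.3e-5
        flux, _ = quad(lambda r: velocity_profile(r, Q, A, zeta) * 2 * np.pi * r,
                       0.0, r_i)
        assert flux == pytest.approx(Q, rel=1e-8)

    def test_outside_lumen_rejected(self):
        A = np.pi * 0.02**2 / 4
        with pytest.raises(ValueError):
            velocity_profile(0.02, 1e-5, A)


@pytest.fixture(scope="module")
def small_geometry():
    return ChainGeometry(n_lymphangions=3, lymphangion_length=0.1, dz=0.01)


class TestSteadyStates:
    def test_poiseuille_oracle(self, small_geometry):
        """Rigid tube, transparent valves, no activation: the steady flow
        matches the series-resistance Hagen-Poiseuille closed form <0.1%."""
        geo = small_geometry
        fl = FluidParams()
        dt, period = 0.01, 1.0
        solver = ChainSolver(
            geometry=geo, fluid=fl, curves=rigid_curves(),
            valve_params=transparent_valves(rv=1.0),
            activation=flat_field(geo, period, dt), p_in=4.0, p_out=3.5,
            dt=dt,
        )
        res = solver.run(n_cycles_max=3, min_cycles=1, steady_tol=1e-6)
        d = 255e-4
        r_tube = 128 * fl.mu * geo.chain_length / (np.pi * d**4)
        r_total = r_tube + 4 * 1.0
        q_expected = 0.5 / r_total
        q = res.Q[:, -1]
        np.testing.assert_allclose(q, q_expected, rtol=1e-3)

    def test_equilibrium_no_drive_no_gradient(self, small_geometry):
        """Pin = Pout, open valves, zero activation: Q -> 0, P uniform."""
        geo = small_geometry
        dt, period = 0.01, 1.0
        solver = ChainSolver(
            geometry=geo, fluid=FluidParams(), curves=calibrate_default_curves(),
            valve_params=transparent_valves(rv=100.0),
            activation=flat_field(geo, period, dt), p_in=3.75, p_out=3.75,
            dt=dt,
        )
        res = solver.run(n_cycles_max=3, min_cycles=1, steady_tol=1e-9)
        assert np.max(np.abs(res.Q[:, -1])) < 1e-12
        np.testing.assert_allclose(res.P[:, -1], 3.75, atol=1e-9)

    def test_resting_pressures_bounded_by_reservoirs(self, small_geometry):
        """Adverse head, functional valves, no activation: steady pressures
        lie within [Pin, Pout] at every node."""
        geo = small_geometry
        dt, period = 0.01, 2.0
        solver = ChainSolver(
            geometry=geo, fluid=FluidParams(), curves=calibrate_default_curves(),
            valve_params=ValveParams(),
            activation=flat_field(geo, period, dt), p_in=3.5, p_out=4.0,
            dt=dt,
        )
        res = solver.run(n_cycles_max=4, min_cycles=2, steady_tol=1e-6)
        assert res.P[:, -1].min() >= 3.5 - 1e-6
        assert res.P[:, -1].max() <= 4.0 + 1e-6


def pulsing_field(geometry, period, dt, depth=1.0):
    """Uniform sinusoidal squeeze (impedance-pump drive for rectification)."""
    n = int(round(period / dt))
    t = np.arange(n) * dt
    col = depth * 0.5 * (1 - np.cos(2 * np.pi * t / period))
    col[np.argmax(col)] = 1.0 * depth  # exact unit max
    values = np.tile(col, (geometry.n_nodes, 1))
    return ActivationField(z_grid=geometry.node_z, t_grid=t,
                           values=values, gamma=1.0, period_T=period)


class TestPumping:
    def test_valve_rectification_yields_forward_flow(self, small_geometry):
        """Uniform pulsation with equal reservoirs: one-way valves rectify
        the oscillation into non-negative net flow."""
        geo = small_geometry
        dt, period = 0.01, 2.0
        solver = ChainSolver(
            geometry=geo, fluid=FluidParams(), curves=calibrate_default_curves(),
            valve_params=ValveParams(), p_in=3.75, p_out=3.75,
            activation=pulsing_field(geo, period, dt, depth=0.5), dt=dt,
        )
        res = solver.run(n_cycles_max=8, min_cycles=3, steady_tol=1e-3)
        assert res.cycle_mean_outflow() >= 0.0

    def test_mass_conservation_across_valve_planes(self, small_geometry):
        geo = small_geometry
        dt, period = 0.01, 2.0
        solver = ChainSolver(
            geometry=geo, fluid=FluidParams(), curves=calibrate_default_curves(),
            valve_params=ValveParams(), p_in=3.5, p_out=4.0,
            activation=pulsing_field(geo, period, dt, depth=0.8), dt=dt,
        )
        res = solver.run(n_cycles_max=8, min_cycles=3, steady_tol=1e-3)
        assert check_mass_conservation(res) < 1e-2

    def test_interior_mass_balance_residual(self, small_geometry):
        """The discretized mass balance holds at every interior node."""
        geo = small_geometry
        dt, period = 0.01, 2.0
        solver = ChainSolver(
            geometry=geo, fluid=FluidParams(), curves=calibrate_default_curves(),
            valve_params=ValveParams(), p_in=3.5, p_out=4.0,
            activation=pulsing_field(geo, period, dt, depth=0.8), dt=dt,
        )
        res = solver.run(n_cycles_max=3, min_cycles=1, steady_tol=1e-9)
        n = res.n_steps
        dAdt = (res.A[:, n] - res.A[:, n - 1]) / dt
        M = geo.nodes_per_lymphangion
        for ell in range(geo.n_lymphangions):
            qf = res.Q[ell * M:(ell + 1) * M + 1, n]
            dq = np.diff(qf)
            w = np.full(M, geo.dz)
            w[0] = w[-1] = geo.dz / 2
            residual = dAdt[ell * M:(ell + 1) * M] * w + dq
            scale = max(np.max(np.abs(qf)), 1e-12)
            assert np.max(np.abs(residual)) / scale < 1e-8

    def test_pump_work_positive_under_drive(self, small_geometry):
        """Cycle-averaged wall work -sum P dV is positive when pumping."""
        geo = small_geometry
        dt, period = 0.01, 2.0
        solver = ChainSolver(
            geometry=geo, fluid=FluidParams(), curves=calibrate_default_curves(),
            valve_params=ValveParams(), p_in=3.5, p_out=4.0,
            activation=pulsing_field(geo, period, dt, depth=0.8), dt=dt,
        )
        res = solver.run(n_cycles_max=8, min_cycles=3, steady_tol=1e-3)
        idx = res.last_cycle()
        w = np.full(geo.n_nodes, geo.dz)
        M = geo.nodes_per_lymphangion
        for ell in range(geo.n_lymphangions):
            w[ell * M] = w[(ell + 1) * M - 1] = geo.dz / 2
        dV = np.diff(res.A[:, idx], axis=1) * w[:, None]
        work = -np.sum(res.P[:, idx[:-1]] * dV)
        assert work > 0


class TestGridConvergence:
    def test_halving_dz_and_dt_changes_outflow_under_2pct(self):
        """Refinement study on a pulsating single-lymphangion pump."""
        results = {}
        for dz, dt in ((0.01, 0.01), (0.005, 0.005)):
            geo = ChainGeometry(n_lymphangions=1, lymphangion_length=0.1, dz=dz)
            solver = ChainSolver(
                geometry=geo, fluid=FluidParams(),
                curves=calibrate_default_curves(),
                valve_params=ValveParams(), p_in=3.5, p_out=4.0,
                activation=pulsing_field(geo, 2.0, dt, depth=0.8), dt=dt,
            )
            res = solver.run(n_cycles_max=6, min_cycles=3, steady_tol=1e-3)
            results[dz] = res.cycle_mean_outflow()
        coarse, fine = results[0.01], results[0.005]
        assert abs(fine - coarse) / max(abs(fine), 1e-15) < 0.02


class TestGeometry:
    def test_non_divisible_dz_rejected(self):
        with pytest.raises(ValueError):
            ChainGeometry(lymphangion_length=0.1, dz=0.003)

    def test_node_counts(self):
        geo = ChainGeometry()
        assert geo.nodes_per_lymphangion == 21
        assert geo.n_nodes == 63
        assert geo.n_valves == 4
        assert geo.node_z[0] == 0.0
        assert geo.node_z[-1] == pytest.approx(0.3)

    def test_determinism_bit_identical_reruns(self):
        """Two runs of the same configuration produce identical arrays."""
        geo = ChainGeometry(n_lymphangions=2, lymphangion_length=0.1, dz=0.01)

        def run_once():
            solver = ChainSolver(
                geometry=geo, fluid=FluidParams(),
                curves=calibrate_default_curves(),
                valve_params=ValveParams(), p_in=3.5, p_out=4.0,
                activation=pulsing_field(geo, 1.0, 0.01, depth=0.7), dt=0.01,
            )
            return solver.run(n_cycles_max=3, min_cycles=2, steady_tol=1e-9)

        a, b = run_once(), run_once()
        assert np.array_equal(a.P, b.P)
        assert np.array_equal(a.Q, b.Q)
        assert np.array_equal(a.A, b.A)
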
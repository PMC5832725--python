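"""Ionic model: flux laws, coupling conservation, adaptive integration."""

from dataclasses import replace

import numpy as np
import pytest

import vasoring as v
from vasoring.cell_ionic import (IntegrationError, NegativeConcentrationError,
                                 all_fluxes, coupling_all, network_rhs)

from _oracles import rk4_fixed, symbolic_flux_values, symbolic_rhs


class TestFluxLaws:
    def test_reversal_potential_zeros(self, cell_params):
        """Voltage-gated fluxes vanish exactly at their reversal potentials."""
        p = cell_params
        for eta, name in ((p.z_Ca1, "Phi_V"), (p.z_NCX, "Phi_N"),
                          (p.z_Cl, "Phi_Cl"), (p.z_K, "Phi_K")):
            fx = all_fluxes(v.CellState(0.3, 1.0, eta), p)
            assert getattr(fx, name) == 0.0

    def test_constant_nscc_influx(self, cell_params):
        fx = all_fluxes(v.CellState(0.5, 1.0, -0.03), cell_params)
        assert fx.Phi_A == 0.6

    def test_socc_off_by_default(self, cell_params):
        assert cell_params.A_S == 0.0
        for zeta in (0.0, 1.0, 10.0):
            assert all_fluxes(v.CellState(0.1, zeta, -0.02), cell_params).Phi_S == 0.0

    def test_serca_half_point(self, cell_params):
        """At chi = x_SR the Hill uptake sits exactly at B_SR / 2 = 200 uM/s."""
        fx = all_fluxes(v.CellState(cell_params.x_SR, 1.0, -0.02), cell_params)
        assert fx.Phi_B == pytest.approx(200.0, abs=1e-12)

    def test_zero_substrate_limits(self, cell_params):
        fx = all_fluxes(v.CellState(0.0, 0.5, -0.02), cell_params)
        assert fx.Phi_B == 0.0 and fx.Phi_C == 0.0 and fx.Phi_D == 0.0
        fx = all_fluxes(v.CellState(0.5, 0.0, -0.02), cell_params)
        assert fx.Phi_C == 0.0 and fx.Phi_L == 0.0

    @pytest.mark.parametrize("state", [(0.1, 0.2, -0.02), (0.5, 2.0, -0.03),
                                       (1.2, 6.0, -0.01), (0.05, 0.5, -0.08)])
    def test_dual_transcription_oracle(self, cell_params, state):
        """Package fluxes match an independently written symbolic transcription."""
        p = replace(cell_params, A_S=0.1)     # exercise the SOCC term too
        ours = np.array(all_fluxes(v.CellState(*state), p))
        theirs = symbolic_flux_values(p, *state)
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_rhs_matches_symbolic_transcription(self, cell_params):
        net = v.CellNetwork(n_cells=1, params=cell_params, adjacency=[[]])
        ours = np.array(v.cell_rhs(net, 0))
        theirs = symbolic_rhs(cell_params, *net.states[0])
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_store_balance_structure(self, cell_params):
        """d zeta/dt involves only the SERCA/CICR/leak cycle: switching those
        three off freezes the store for any membrane state."""
        p = replace(cell_params, B_SR=0.0, C_Ry=0.0, L_SR=0.0)
        net = v.CellNetwork(n_cells=1, params=p, adjacency=[[]])
        for state in [(0.1, 0.2, -0.02), (0.9, 3.0, -0.05)]:
            net.states[0] = state
            assert v.cell_rhs(net, 0)[1] == 0.0

    def test_nonfinite_state_rejected(self, cell_params):
        with pytest.raises(IntegrationError):
            all_fluxes(v.CellState(np.nan, 0.2, -0.02), cell_params)
        with pytest.raises(NegativeConcentrationError):
            v.store_exchange(v.CellState(-0.1, 0.2, -0.02), cell_params)


class TestCoupling:
    def test_no_gradients_no_currents(self, cell_params):
        net = v.chain_network(4, cell_params)
        for i in range(4):
            assert v.coupling_currents(i, net) == (0.0, 0.0)

    def test_zero_diffusivity(self, cell_params):
        p = replace(cell_params, alpha_C=0.0, alpha_V=0.0)
        net = v.chain_network(3, p)
        net.states[:, 0] = [0.1, 0.5, 0.9]
        net.states[:, 2] = [-0.02, -0.05, -0.01]
        for i in range(3):
            assert v.coupling_currents(i, net) == (0.0, 0.0)

    def test_two_cell_antisymmetry(self, cell_params):
        net = v.chain_network(2, replace(cell_params, alpha_C=1.0))
        net.states[:, 0] = [0.1, 0.3]
        j0, _ = v.coupling_currents(0, net)
        j1, _ = v.coupling_currents(1, net)
        assert j0 == pytest.approx(0.2)
        assert j0 == -j1

    def test_graph_conservation_on_ring_mesh(self, cell_params, geometry):
        """Sum of coupling currents vanishes exactly even with heterogeneous
        neighbour counts (boundary cells of the structured ring)."""
        mesh = v.build_ring_mesh(geometry, (3, 10, 4))
        rng = np.random.default_rng(7)
        net = v.CellNetwork(n_cells=mesh.n_elements, params=cell_params,
                            adjacency=mesh.adjacency)
        net.states[:, 0] = rng.uniform(0.05, 1.0, mesh.n_elements)
        net.states[:, 2] = rng.uniform(-0.08, 0.0, mesh.n_elements)
        j = coupling_all(net)
        assert abs(j[:, 0].sum()) < 1e-12
        assert abs(j[:, 1].sum()) < 1e-14

    def test_dangling_neighbour_rejected(self, cell_params):
        with pytest.raises(ValueError, match="dangling"):
            v.CellNetwork(n_cells=2, params=cell_params, adjacency=[[5], [0]])

    def test_asymmetric_adjacency_rejected(self, cell_params):
        with pytest.raises(ValueError, match="asymmetric"):
            v.CellNetwork(n_cells=2, params=cell_params, adjacency=[[1], []])


class TestIntegration:
    def test_zero_rhs_constant_states(self, cell_params):
        p = replace(cell_params, Phi_A=0.0, A_S=0.0, E_Ca=0.0, E_NCX=0.0,
                    B_SR=0.0, C_Ry=0.0, L_SR=0.0, D_EX=0.0, E_Cl=0.0, E_K=0.0)
        net = v.CellNetwork(n_cells=2, params=p,
                            adjacency=[[1], [0]])
        t, traj = v.integrate_network(net, (0.0, 1.0), 0.1)
        np.testing.assert_array_equal(traj[-1], traj[0])

    def test_single_cell_vs_reference_integrator(self, cell_params):
        """Adaptive Runge-Kutta-Merson vs scipy DOP853 at rtol 1e-10 over
        100 s: max |Delta chi| below 1e-4 uM at default tolerances."""
        from scipy.integrate import solve_ivp
        net = v.CellNetwork(n_cells=1, params=cell_params, adjacency=[[]])
        t, traj = v.integrate_network(net, (0.0, 100.0), 0.05)
        ref_net = v.CellNetwork(n_cells=1, params=cell_params, adjacency=[[]])

        def rhs(tt, y):
            return network_rhs(ref_net, y.reshape(1, 3)).ravel()

        sol = solve_ivp(rhs, (0, 100.0), list(v.cell_ionic.DEFAULT_INITIAL_STATE),
                        method="DOP853", rtol=1e-10, atol=1e-12, t_eval=t)
        assert np.max(np.abs(traj[:, 0, 0] - sol.y[0])) < 1e-4

    def test_adaptive_vs_fixed_step_rk4(self, cell_params):
        """10 s single-cell run: adaptive scheme within 1e-4 uM of fixed-step
        RK4 at dt = 1e-4 s."""
        net = v.CellNetwork(n_cells=1, params=cell_params, adjacency=[[]])
        t, traj = v.integrate_network(net, (0.0, 10.0), 0.1)
        ref_net = v.CellNetwork(n_cells=1, params=cell_params, adjacency=[[]])

        def rhs(tt, y):
            return network_rhs(ref_net, y.reshape(1, 3)).ravel()

        y_ref = rk4_fixed(rhs, list(v.cell_ionic.DEFAULT_INITIAL_STATE),
                          10.0, 1e-4)
        assert np.max(np.abs(traj[-1, 0] - y_ref.reshape(3))[0]) < 1e-4

    def test_sustained_oscillation_at_raised_influx(self, cell_params):
        """A single uncoupled cell with Phi_A = 0.8 uM/s shows sustained
        periodic Ca2+ oscillation; the period matches the frozen reference
        value from a high-accuracy integration (1.2648 s)."""
        from vasoring.analysis import peak_times
        p = replace(cell_params, Phi_A=0.8)
        net = v.CellNetwork(n_cells=1, params=p, adjacency=[[]])
        t, traj = v.integrate_network(net, (0.0, 120.0), 0.01)
        chi = traj[:, 0, 0]
        pk = peak_times(t, chi)
        pk = pk[pk > 60.0]
        assert len(pk) >= 20, "oscillation died out"
        period = float(np.diff(pk).mean())
        assert period == pytest.approx(1.2648, rel=2e-3)

    def test_nonnegative_concentrations_long_run(self, cell_params):
        """chi and zeta stay nonnegative over a 1000 s simulation."""
        net = v.CellNetwork(n_cells=1, params=cell_params, adjacency=[[]])
        t, traj = v.integrate_network(net, (0.0, 1000.0), 0.25)
        assert traj[:, 0, 0].min() >= 0.0
        assert traj[:, 0, 1].min() >= 0.0
        assert np.abs(traj[:, 0, 2]).max() < 0.2

    def test_chain_synchronization(self, cell_params):
        """Coupling (alpha = 1/s) raises the phase order of a heterogeneous
        3-cell chain relative to the uncoupled run."""
        from vasoring.analysis import phase_order_parameter
        phi = np.array([0.55, 0.65, 0.75])
        orders = {}
        for a in (0.0, 1.0):
            p = replace(cell_params, Phi_A=phi, alpha_C=a, alpha_V=a)
            net = v.chain_network(3, p)
            t, traj = v.integrate_network(net, (0.0, 80.0), 0.01)
            orders[a] = phase_order_parameter(t, traj[:, :, 0], t_min=40.0)
        assert orders[1.0] > orders[0.0] + 0.05
        assert orders[1.0] > 0.8

    def test_invalid_dt_rejected(self, cell_params):
        net = v.CellNetwork(n_cells=1, params=cell_params, adjacency=[[]])
        with pytest.raises(ValueError):
            v.integrate_network(net, (0.0, 1.0), 0.0)
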
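"""Hyperelastic finite elements: kinematics, stresses, tangents, Newton, hooks."""

from dataclasses import replace

import numpy as np
import pytest

import vasoring as v
from vasoring.continuum_fe import (ElementInversionError, NewtonError,
                                   _solve_at, pk_stress, strain_energy_density)

from conftest import make_strip_system
from _oracles import uniaxial_homogeneous_force

A0X = np.array([1.0, 0.0, 0.0])


def _rotation(axis, angle):
    axis = np.asarray(axis, dtype=float) / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * k @ k


class TestKinematics:
    def test_reference_configuration(self):
        mesh = v.build_strip_mesh(1, 1, 1)
        kin = v.kinematics_at_gp(mesh.nodes[mesh.elements[0]],
                                 np.zeros((8, 3)), 0, A0X)
        np.testing.assert_allclose(kin.F, np.eye(3))
        assert kin.J == pytest.approx(1.0)
        assert kin.I4_bar == pytest.approx(1.0)
        assert kin.lam == pytest.approx(1.0)

    def test_pure_rotation_is_strain_free(self):
        mesh = v.build_strip_mesh(1, 1, 1)
        coords = mesh.nodes[mesh.elements[0]]
        r = _rotation([1, 2, 3], 0.7)
        u = coords @ r.T - coords
        kin = v.kinematics_at_gp(coords, u, 3, A0X)
        assert kin.J == pytest.approx(1.0, abs=1e-12)
        assert kin.I1_bar == pytest.approx(3.0, abs=1e-12)
        assert kin.I4_bar == pytest.approx(1.0, abs=1e-12)

    def test_isochoric_uniaxial_stretch(self):
        """F = diag(1.2, 1/sqrt(1.2), 1/sqrt(1.2)) gives I4_bar = 1.44."""
        mesh = v.build_strip_mesh(1, 1, 1)
        coords = mesh.nodes[mesh.elements[0]]
        f = np.diag([1.2, 1.2 ** -0.5, 1.2 ** -0.5])
        u = coords @ f.T - coords
        kin = v.kinematics_at_gp(coords, u, 0, A0X)
        assert kin.J == pytest.approx(1.0, abs=1e-12)
        assert kin.I4_bar == pytest.approx(1.44, abs=1e-12)

    def test_inverted_element_diagnosed(self):
        mesh = v.build_strip_mesh(1, 1, 1)
        coords = mesh.nodes[mesh.elements[0]]
        u = -2.0 * coords          # reflects the element
        with pytest.raises(ElementInversionError):
            v.kinematics_at_gp(coords, u, 0, A0X)


class TestStressAndTangent:
    def test_reference_state_stress_free(self, tissue_params):
        assert strain_energy_density(np.eye(3), A0X, tissue_params) == \
            pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(pk_stress(np.eye(3), A0X, tissue_params),
                                   0.0, atol=1e-12)

    @pytest.mark.parametrize("active", [None, (1500.0, -0.04)])
    def test_analytic_stress_matches_energy_gradient(self, tissue_params,
                                                     rng, active):
        """P = dPsi/dF by central finite differences, rel. err < 1e-6."""
        f = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        assert np.linalg.det(f) > 0
        p = pk_stress(f, A0X, tissue_params, active)
        fd = np.zeros((3, 3))
        h = 1e-5
        for i in range(3):
            for j in range(3):
                fp, fm = f.copy(), f.copy()
                fp[i, j] += h
                fm[i, j] -= h
                fd[i, j] = (strain_energy_density(fp, A0X, tissue_params, active)
                            - strain_energy_density(fm, A0X, tissue_params,
                                                    active)) / (2 * h)
        np.testing.assert_allclose(p, fd, rtol=1e-6, atol=1e-8)

    def test_vanishing_fibre_stiffness_recovers_isotropy(self):
        f = np.diag([1.3, 0.9, 0.9])
        tis = v.TissueParams(c_p1=1e-12)
        p_x = pk_stress(f, A0X, tis)
        p_y = pk_stress(f, np.array([0.0, 1.0, 0.0]), tis)
        np.testing.assert_allclose(p_x, p_y, atol=1e-10)

    def test_objectivity_under_superposed_rotation(self, tissue_params):
        f = np.diag([1.2, 0.95, 0.9])
        r = _rotation([0.3, -1, 2], 1.1)
        e1 = strain_energy_density(f, A0X, tissue_params)
        e2 = strain_energy_density(r @ f, A0X, tissue_params)
        assert e2 == pytest.approx(e1, rel=1e-10)

    def test_fibre_exponential_overflow_diagnosed(self, tissue_params):
        with pytest.raises(FloatingPointError, match="overflow"):
            strain_energy_density(np.diag([50.0, 1.0, 1.0]), A0X, tissue_params)

    @pytest.mark.parametrize("active", [None, "cu"])
    def test_assembled_tangent_vs_finite_differenced_residual(self, rng, active):
        """Complex-step tangent vs central differences of the assembled
        internal force on a randomly perturbed single element state."""
        mesh, fes = make_strip_system(1)
        act = None
        if active == "cu":
            act = (np.full((1, 8), 900.0), np.full((1, 8), -0.03))
        u = 0.05 * rng.standard_normal((mesh.n_nodes, 3))
        k = fes.tangent(u, act).toarray()
        h = 1e-6
        for dof in rng.choice(24, size=6, replace=False):
            up, um = u.reshape(-1).copy(), u.reshape(-1).copy()
            up[dof] += h
            um[dof] -= h
            fd = (fes.internal_force(up.reshape(-1, 3), act)
                  - fes.internal_force(um.reshape(-1, 3), act)).reshape(-1) / (2 * h)
            np.testing.assert_allclose(k[:, dof], fd, rtol=1e-4, atol=1e-7)

    def test_assembled_tangent_symmetric(self, rng):
        mesh, fes = make_strip_system(2)
        u = 0.05 * rng.standard_normal((mesh.n_nodes, 3))
        k = fes.tangent(u).toarray()
        assert np.abs(k - k.T).max() <= 1e-8 * np.abs(k).max()

    def test_rigid_translation_leaves_residual_unchanged(self, rng):
        mesh, fes = make_strip_system(2)
        u = 0.03 * rng.standard_normal((mesh.n_nodes, 3))
        f1 = fes.internal_force(u)
        f2 = fes.internal_force(u + np.array([0.4, -0.2, 0.7]))
        np.testing.assert_allclose(f1, f2, atol=1e-11)


class TestNewton:
    def test_starting_at_solution_converges_immediately(self):
        mesh, fes = make_strip_system(1, stretch=1.15)
        sol = fes.newton_solve(np.zeros((mesh.n_nodes, 3)))
        sol2 = fes.newton_solve(sol.u)
        assert sol2.converged and sol2.iterations == 1

    def test_quadratic_convergence_tail(self):
        """Near the solution the residual drops quadratically."""
        mesh, fes = make_strip_system(1, stretch=1.2)
        sol = fes.newton_solve(np.zeros((mesh.n_nodes, 3)), rtol=1e-13,
                               atol=1e-14, line_search=False)
        h = [r for r in sol.residual_history if r > 1e-13]
        assert len(h) >= 3
        # ratio test on the last consecutive triple
        r0, r1, r2 = h[-3], h[-2], h[-1]
        assert r2 / r1 < 0.2 * r1 / r0 or r2 < 1e-11

    def test_equilibrium_state_has_small_residual(self):
        mesh, fes = make_strip_system(1, stretch=1.1)
        sol = fes.newton_solve(np.zeros((mesh.n_nodes, 3)))
        assert sol.residual_norm < 1e-8

    def test_oversized_increment_fails_then_substepping_succeeds(self, geometry):
        mesh = v.build_ring_mesh(geometry, (1, 8, 2))
        fes = v.FESystem(mesh.nodes, mesh.elements, v.TissueParams(),
                         v.circumferential_fibre(mesh))
        base = v.ring_model.myograph_bcs(mesh)
        hook = mesh.node_sets["hook_contact"]
        with pytest.raises(NewtonError):
            _solve_at(fes, hook, base, 0.3, None)
        sol, d, f = v.loading_phase(fes, hook, base, 0.05,
                                    symmetry_factor=mesh.symmetry_factor)
        assert f == pytest.approx(0.05, rel=5e-3)

    def test_nonconvergence_carries_history(self):
        mesh, fes = make_strip_system(1, stretch=1.5)
        with pytest.raises(NewtonError) as err:
            fes.newton_solve(np.zeros((mesh.n_nodes, 3)), max_iter=2)
        assert len(err.value.history) == 2


class TestHookForceAndLoading:
    def test_unloaded_ring_zero_force(self, geometry):
        mesh = v.build_ring_mesh(geometry, (1, 8, 2))
        fes = v.FESystem(mesh.nodes, mesh.elements, v.TissueParams(),
                         v.circumferential_fibre(mesh))
        fes.set_dirichlet(v.ring_model.myograph_bcs(mesh))
        sol = fes.newton_solve(np.zeros((mesh.n_nodes, 3)))
        assert v.hook_force(fes, sol, mesh.node_sets["hook_contact"]) == \
            pytest.approx(0.0, abs=1e-10)

    def test_global_equilibrium(self, geometry):
        """The assembled internal forces sum to zero over the whole mesh
        (all reactions balance)."""
        mesh = v.build_ring_mesh(geometry, (1, 8, 2))
        fes = v.FESystem(mesh.nodes, mesh.elements, v.TissueParams(),
                         v.circumferential_fibre(mesh))
        base = v.ring_model.myograph_bcs(mesh)
        sol = _march(fes, mesh.node_sets["hook_contact"], base, 0.05, None)
        f = fes.internal_force(sol.u)
        assert np.abs(f.sum(axis=0)).max() < 1e-8 * np.abs(f).max()

    def test_empty_hook_set_rejected(self):
        mesh, fes = make_strip_system(1)
        sol = fes.newton_solve(np.zeros((mesh.n_nodes, 3)))
        with pytest.raises(ValueError, match="empty"):
            v.hook_force(fes, sol, [], symmetry_factor=1.0)

    def test_passive_strip_matches_semianalytic_uniaxial(self, tissue_params):
        """Single-element uniaxial bar vs the homogeneous penalty-
        incompressible minimisation oracle, rel. err < 1e-6."""
        stretch = 1.25
        mesh, fes = make_strip_system(1, stretch=stretch)
        sol = fes.newton_solve(np.zeros((mesh.n_nodes, 3)), rtol=1e-12)
        f_fe = v.hook_force(fes, sol, mesh.node_sets["hook_contact"],
                            symmetry_factor=1.0)
        f_ref, lt = uniaxial_homogeneous_force(stretch, tissue_params)
        assert f_fe == pytest.approx(f_ref, rel=1e-6)
        # the FE transverse stretch matches the minimiser as well
        kin = fes.kinematics(sol.u)
        lam_t = np.sqrt(kin["J"].mean() / stretch * 1.0)
        assert lam_t == pytest.approx(lt, rel=1e-6)

    def test_active_strip_force_matches_homogeneous_oracle(self, tissue_params,
                                                           cu_params):
        """Isometric active bar: hook force equals the homogeneous active
        response (CU stress times reference cross-section after transverse
        relaxation)."""
        n_att, u_fs = 0.4, -0.02
        k_act = cu_params.mu_a * v.overlap(u_fs, cu_params) * n_att
        mesh, fes = make_strip_system(1, stretch=1.0)
        act = (np.full((1, 8), k_act), np.full((1, 8), u_fs))
        sol = fes.newton_solve(np.zeros((mesh.n_nodes, 3)), active=act,
                               rtol=1e-12)
        f_fe = v.hook_force(fes, sol, mesh.node_sets["hook_contact"],
                            symmetry_factor=1.0, active=act)
        f_ref, _ = uniaxial_homogeneous_force(1.0, tissue_params,
                                              active=(k_act, u_fs))
        assert f_fe == pytest.approx(f_ref, rel=1e-6)

    def test_loading_phase_zero_target_is_identity(self, geometry):
        mesh = v.build_ring_mesh(geometry, (1, 8, 2))
        fes = v.FESystem(mesh.nodes, mesh.elements, v.TissueParams(),
                         v.circumferential_fibre(mesh))
        sol, d, f = v.loading_phase(fes, mesh.node_sets["hook_contact"],
                                    v.ring_model.myograph_bcs(mesh), 0.0)
        assert d == 0.0 and f == 0.0
        np.testing.assert_allclose(sol.u, 0.0, atol=1e-12)

    def test_hook_force_monotone_in_displacement(self, geometry):
        """Passive stiffness: larger hook separation, larger force (sampled
        in the membrane-stretching regime)."""
        mesh = v.build_ring_mesh(geometry, (1, 8, 2))
        fes = v.FESystem(mesh.nodes, mesh.elements, v.TissueParams(),
                         v.circumferential_fibre(mesh))
        base = v.ring_model.myograph_bcs(mesh)
        hook = mesh.node_sets["hook_contact"]
        forces = []
        u, d_prev = None, 0.0
        for d in np.linspace(0.02, 0.2, 6):
            sol = _march(fes, hook, base, d, u, dd=0.01, d_start=d_prev)
            u, d_prev = sol.u, d
            forces.append(v.hook_force(fes, sol, hook,
                                       symmetry_factor=mesh.symmetry_factor))
        assert np.all(np.diff(forces) > 0)


def _march(fes, hook, base, d_target, u_start, dd=0.02, d_start=0.0):
    u = u_start if u_start is not None else np.zeros((fes.n_nodes, 3))
    # march in shared steps from d_start up to d_target
    cur = d_start
    sol = None
    while cur < d_target - 1e-12:
        step = min(dd, d_target - cur)
        try:
            sol = _solve_at(fes, hook, base, cur + step, u)
        except NewtonError:
            dd = step / 2
            if dd < 1e-4:
                raise
            continue
        cur += step
        u = sol.u
        dd = min(1.5 * dd, 0.03)
    return sol


class TestIncompressibilityPenalty:
    def test_j_approaches_one_as_kappa_grows(self):
        """|J - 1| shrinks monotonically as the penalty is scaled x10, x100."""
        devs = []
        for scale in (1.0, 10.0, 100.0):
            tis = v.TissueParams(kappa=4.0 * scale)
            mesh, fes = make_strip_system(1, stretch=1.3, tissue=tis)
            sol = fes.newton_solve(np.zeros((mesh.n_nodes, 3)))
            devs.append(abs(fes.kinematics(sol.u)["J_bar"] - 1.0).max())
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < devs[0] / 20


class TestSymmetryReduction:
    def test_full_ring_matches_one_eighth(self, geometry):
        """A full-ring model with mirrored resolution reproduces the reduced
        one-eighth hook force within 0.1%."""
        res8 = (1, 6, 2)
        d = 0.12
        mesh8 = v.build_ring_mesh(geometry, res8)
        fes8 = v.FESystem(mesh8.nodes, mesh8.elements, v.TissueParams(),
                          v.circumferential_fibre(mesh8))
        base8 = v.ring_model.myograph_bcs(mesh8)
        hook8 = mesh8.node_sets["hook_contact"]
        sol8 = _march(fes8, hook8, base8, d, None)
        f8 = v.hook_force(fes8, sol8, hook8, symmetry_factor=4.0)

        meshf = v.build_full_ring_mesh(geometry, res8)
        fesf = v.FESystem(meshf.nodes, meshf.elements, v.TissueParams(),
                          v.circumferential_fibre(meshf))
        basef = {}
        for n in meshf.node_sets["mid_z"]:
            basef[(int(n), 2)] = 0.0
        for n in meshf.node_sets["axis_y"]:
            basef[(int(n), 1)] = 0.0
        for n in meshf.node_sets["hook_px"]:
            basef[(int(n), 1)] = 0.0
        for n in meshf.node_sets["hook_mx"]:
            basef[(int(n), 1)] = 0.0
        hook_px = meshf.node_sets["hook_px"]
        hook_mx = meshf.node_sets["hook_mx"]
        u = np.zeros((meshf.n_nodes, 3))
        cur, dd = 0.0, 0.02
        while cur < d - 1e-12:
            step = min(dd, d - cur)
            bcs = dict(basef)
            for n in hook_px:
                bcs[(int(n), 0)] = cur + step
            for n in hook_mx:
                bcs[(int(n), 0)] = -(cur + step)
            fesf.set_dirichlet(bcs)
            try:
                solf = fesf.newton_solve(u)
            except NewtonError:
                dd = step / 2
                if dd < 1e-4:
                    raise
                continue
            cur += step
            u = solf.u
            dd = min(1.5 * dd, 0.03)
        ff = v.hook_force(fesf, solf, hook_px, symmetry_factor=1.0)
        assert ff == pytest.approx(f8, rel=1e-3)
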
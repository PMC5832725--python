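"""Independent transcriptions and brute-force oracles used by the tests.

The symbolic flux laws below were written down separately from the package
implementation (sympy expressions, different algebraic arrangement) so that
a typo in either copy shows up as a mismatch.
"""

import numpy as np
import sympy as sp

_CHI, _ZETA, _ETA = sp.symbols("chi zeta eta")


def _symbolic_fluxes(p):
    """All ten concentration currents as sympy expressions of (chi, zeta, eta)."""
    c, z, e = _CHI, _ZETA, _ETA
    phi_a = sp.Float(p.Phi_A)
    phi_s = p.A_S / (1 + (z / p.zeta_S) ** 2)
    phi_v = p.E_Ca * (p.z_Ca1 - e) * sp.exp((e - p.z_Ca2) / p.R_Ca) \
        / (sp.exp((e - p.z_Ca2) / p.R_Ca) + 1)
    phi_n = p.E_NCX * (e - p.z_NCX) / (1 + p.x_NCX / c)
    phi_b = p.B_SR / (1 + (p.x_SR / c) ** p.n_SR)
    phi_c = p.C_Ry / (1 + (p.y_Ry / z) ** p.m_Ry) / (1 + (p.x_Ry / c) ** p.p_Ry)
    phi_l = p.L_SR * z
    phi_d = p.D_EX * c ** p.k_Ex * (p.R_Ex + e - p.z_Ex) / p.R_Ex
    phi_cl = p.E_Cl * (e - p.z_Cl) * (1 if p.x_Cl == 0 else c / (c + p.x_Cl))
    phi_k = p.E_K * (e - p.z_K) / (1 + sp.exp((p.z_Ca3 - e) / p.R_K)) \
        * (1 if p.beta_K == 0 else c / (c + p.beta_K))
    return (phi_a, phi_s, phi_v, phi_n, phi_b, phi_c, phi_l, phi_d, phi_cl, phi_k)


def symbolic_flux_values(p, chi, zeta, eta):
    """Evaluate the independent transcription at one state, high precision."""
    subs = {_CHI: sp.Float(chi, 30), _ZETA: sp.Float(zeta, 30),
            _ETA: sp.Float(eta, 30)}
    return np.array([float(sp.N(f.subs(subs), 25)) for f in _symbolic_fluxes(p)])


def symbolic_rhs(p, chi, zeta, eta, j_ca=0.0, j_v=0.0):
    """Independent transcription of the three balance equations."""
    a, s, v, n, b, c, l, d, cl, k = symbolic_flux_values(p, chi, zeta, eta)
    return np.array([a + s + v + n - b + c + l - d + j_ca,
                     b - c - l,
                     p.gamma * (2 * v - n - cl - k) + j_v])


def rk4_fixed(f, y0, t_end, dt):
    """Classical fixed-step RK4 (the cross-check for the adaptive scheme)."""
    y = np.array(y0, dtype=float)
    n = int(round(t_end / dt))
    t = 0.0
    for _ in range(n):
        k1 = f(t, y)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y


def uniaxial_homogeneous_force(stretch, tissue, active=None, area=1.0):
    """Semi-analytic uniaxial response: minimise the energy density over the
    transverse stretch at fixed axial stretch (fibres along x), then take the
    axial force as the envelope derivative d psi / d lambda_x * area."""
    from scipy.optimize import minimize_scalar
    from vasoring.continuum_fe import strain_energy_density

    a0 = np.array([1.0, 0.0, 0.0])

    def psi(lx, lt):
        return strain_energy_density(np.diag([lx, lt, lt]), a0, tissue, active)

    def minimised(lx):
        r = minimize_scalar(lambda lt: psi(lx, lt), bounds=(0.2, 3.0),
                            method="bounded", options={"xatol": 1e-12})
        return r.x, r.fun

    h = 1e-6
    lt, _ = minimised(stretch)
    # envelope theorem: at the optimal transverse stretch, d psi/d lx is partial
    dpsi = (psi(stretch + h, lt) - psi(stretch - h, lt)) / (2 * h)
    return dpsi * area, lt
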
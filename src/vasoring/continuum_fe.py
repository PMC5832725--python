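"""Quasi-static incompressible fibre-reinforced hyperelastic finite elements.

Trilinear (Q1) hexahedra with 2x2x2 Gauss quadrature and an element-constant
pressure/dilatation treatment: the volumetric penalty energy is evaluated on
the element-mean Jacobian (the condensed Q1/P0 three-field formulation), so
the element pressure is p = kappa * (J_bar - 1).

The strain energy per unit reference volume is split as

    Psi = Psi_vol(J_bar) + Psi_p(I1_bar, I4_bar) + Psi_a(I4_bar)

with the isochoric invariants I1_bar = J^(-2/3) tr(C), I4_bar = J^(-2/3)
a0.C.a0 (a0 = unit fibre direction, circumferential in the ring), and

    Psi_vol = kappa/2 (J_bar - 1)^2
    Psi_p   = mu_p/2 (I1_bar - 3)
            + c_p1/(2 c_p2) [exp(c_p2 (I4_bar - 1)^2) - 1]
    Psi_a   = mu_a/2 L_fo (n_AMp + n_AM) (lam - 1 - u_fs)^2,  lam = sqrt(I4)

(the active term is supplied by the contractile-unit model as frozen
per-Gauss-point coefficients; its stretch is the geometric fibre stretch
lam = |F a0|, the full fourth invariant, since the contractile-unit length
ratio is a physical length change -- the deviatoric invariant only
coincides with it at exact incompressibility, and coupling the very stiff
active term to J through the isochoric split destabilises the weakly
penalised tissue).  Stresses are analytic energy derivatives;
the consistent tangent is obtained by complex-step differentiation of the
analytically assembled element internal-force vector, which is exact to
machine precision and keeps Newton quadratic.  The nonlinear system is
solved by Newton-Raphson with optional backtracking; the linear solver is a
deterministic sparse direct factorisation.

Loads enter exclusively through prescribed displacements (isometric
myograph rings are displacement-controlled); reaction forces are read off
the internal-force vector at constrained nodes.  Units: mm, kPa, so forces
come out in mN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TissueParams",
    "Kinematics",
    "FESolution",
    "FESystem",
    "ElementInversionError",
    "NewtonError",
    "kinematics_at_gp",
    "strain_energy_density",
    "pk_stress",
    "hook_force",
    "loading_phase",
]

_CS_H = 1e-30  # complex-step perturbation
_EXP_GUARD = 60.0


class ElementInversionError(RuntimeError):
    def __init__(self, element: int, j: float):
        super().__init__(f"element {element} inverted (J={j:.4g} <= 0)")
        self.element = element


class NewtonError(RuntimeError):
    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


@dataclass
class TissueParams:
    """Passive/volumetric tissue constants (defaults: reference set)."""

    kappa: float = 4.0    # bulk (penalty) modulus (kPa)
    mu_p: float = 0.84    # passive shear modulus (kPa)
    c_p1: float = 3.15    # fibre stiffness scale (kPa)
    c_p2: float = 0.035   # fibre exponential exponent (-)
    mu_a: float = 5301.0  # active shear modulus (kPa), shared with the CU model

    def __post_init__(self):
        if self.kappa <= 0 or self.mu_p <= 0 or self.c_p1 <= 0:
            raise ValueError("kappa, mu_p, c_p1 must be positive")


@dataclass
class Kinematics:
    """Deformation measures at one Gauss point."""

    F: np.ndarray
    J: float
    C_bar: np.ndarray
    I1_bar: float
    I4_bar: float
    lam: float


@dataclass
class FESolution:
    """Converged (or failed) nonlinear solution."""

    u: np.ndarray                  # nodal displacements (nn, 3), mm
    pressure: np.ndarray           # element pressures kappa*(J_bar-1), kPa
    converged: bool
    residual_norm: float
    iterations: int
    residual_history: list = field(default_factory=list)


# --- small complex-safe 3x3 helpers (vectorised over leading axes) ---------

def _det3(a):
    return (a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
            - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
            + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]))


def _inv3(a):
    det = _det3(a)
    out = np.empty_like(a)
    out[..., 0, 0] = a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1]
    out[..., 0, 1] = a[..., 0, 2] * a[..., 2, 1] - a[..., 0, 1] * a[..., 2, 2]
    out[..., 0, 2] = a[..., 0, 1] * a[..., 1, 2] - a[..., 0, 2] * a[..., 1, 1]
    out[..., 1, 0] = a[..., 1, 2] * a[..., 2, 0] - a[..., 1, 0] * a[..., 2, 2]
    out[..., 1, 1] = a[..., 0, 0] * a[..., 2, 2] - a[..., 0, 2] * a[..., 2, 0]
    out[..., 1, 2] = a[..., 0, 2] * a[..., 1, 0] - a[..., 0, 0] * a[..., 1, 2]
    out[..., 2, 0] = a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]
    out[..., 2, 1] = a[..., 0, 1] * a[..., 2, 0] - a[..., 0, 0] * a[..., 2, 1]
    out[..., 2, 2] = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    return out / det[..., None, None]


# --- reference element --------------------------------------------------------

_XI = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)
_GP = np.array([[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)],
               dtype=float) / np.sqrt(3.0)
N_GP = 8


def _shape_grads_ref():
    """dN_a/dxi at each Gauss point: array (8 gp, 8 nodes, 3)."""
    g = np.empty((N_GP, 8, 3))
    for q, (x, y, z) in enumerate(_GP):
        for a, (xa, ya, za) in enumerate(_XI):
            g[q, a, 0] = 0.125 * xa * (1 + ya * y) * (1 + za * z)
            g[q, a, 1] = 0.125 * ya * (1 + xa * x) * (1 + za * z)
            g[q, a, 2] = 0.125 * za * (1 + xa * x) * (1 + ya * y)
    return g


_DNDXI = _shape_grads_ref()


def shape_values(xi):
    """Trilinear shape functions at local coordinate xi (3,)."""
    return 0.125 * np.prod(1.0 + _XI * np.asarray(xi), axis=1)


# --- constitutive core (works on complex arrays) ------------------------------

def _fibre_dpsi(i4b, tis: TissueParams):
    """d(passive fibre energy)/dI4_bar = c_p1 (I4b-1) exp(c_p2 (I4b-1)^2)."""
    q = tis.c_p2 * (i4b - 1.0) ** 2
    if np.any(np.real(q) > _EXP_GUARD):
        raise FloatingPointError("fibre exponential overflow: stretch far out of range")
    return tis.c_p1 * (i4b - 1.0) * np.exp(q)


def _active_dpsi(i4, k_act, u_fs):
    """d(active energy)/dI4 with frozen CU coefficients.

    The contractile-unit stretch is the geometric fibre stretch
    lam = |F a0| = sqrt(I4) (full invariant: a length ratio, unlike the
    deviatoric one when J != 1).  k_act = mu_a * L_fo(u_fs) * (n_AMp + n_AM)
    per Gauss point.
    """
    lam = np.sqrt(i4)
    return k_act * (lam - 1.0 - u_fs) / (2.0 * lam)


# --- single-point reference API (used by tests and the spec surface) ----------

def kinematics_at_gp(coords: np.ndarray, u: np.ndarray, gp: int,
                     a0: np.ndarray) -> Kinematics:
    """Deformation measures at Gauss point ``gp`` of one hexahedron.

    ``coords``/``u``: (8, 3) reference coordinates and displacements;
    ``a0``: unit fibre direction.
    """
    dndxi = _DNDXI[gp]
    j0 = np.einsum("ai,aj->ij", coords, dndxi)
    det0 = _det3(j0)
    if det0 <= 0:
        raise ElementInversionError(0, float(det0))
    grad = dndxi @ _inv3(j0)          # dN_a/dX (8, 3)
    f = np.eye(3) + np.einsum("ai,aj->ij", u, grad)
    j = float(_det3(f))
    if j <= 0:
        raise ElementInversionError(0, j)
    c_bar = j ** (-2.0 / 3.0) * f.T @ f
    i1b = float(np.trace(c_bar))
    i4b = float(a0 @ c_bar @ a0)
    return Kinematics(F=f, J=j, C_bar=c_bar, I1_bar=i1b, I4_bar=i4b,
                      lam=float(np.sqrt(i4b)))


def strain_energy_density(F: np.ndarray, a0: np.ndarray, tis: TissueParams,
                          active: tuple[float, float] | None = None) -> float:
    """Psi per unit reference volume at a homogeneous deformation gradient.

    ``active = (k_act, u_fs)`` adds the contractile-unit energy.  The
    volumetric term uses the pointwise J (equal to the element mean for
    homogeneous states).
    """
    j = _det3(np.asarray(F))
    if np.real(j) <= 0:
        raise ElementInversionError(0, float(np.real(j)))
    c = np.swapaxes(F, -1, -2) @ F
    i1b = j ** (-2.0 / 3.0) * np.trace(c)
    i4b = j ** (-2.0 / 3.0) * (a0 @ c @ a0)
    q = tis.c_p2 * (i4b - 1.0) ** 2
    if np.real(q) > _EXP_GUARD:
        raise FloatingPointError("fibre exponential overflow")
    psi = (0.5 * tis.kappa * (j - 1.0) ** 2
           + 0.5 * tis.mu_p * (i1b - 3.0)
           + tis.c_p1 / (2.0 * tis.c_p2) * (np.exp(q) - 1.0))
    if active is not None:
        k_act, u_fs = active
        lam = np.sqrt(a0 @ c @ a0)      # CU stretch = |F a0| (full invariant)
        psi = psi + 0.5 * k_act * (lam - 1.0 - u_fs) ** 2
    return psi


def pk_stress(F: np.ndarray, a0: np.ndarray, tis: TissueParams,
              active: tuple[float, float] | None = None) -> np.ndarray:
    """Analytic first Piola-Kirchhoff stress P = dPsi/dF at one state."""
    F = np.asarray(F)
    j = _det3(F)
    if np.real(j) <= 0:
        raise ElementInversionError(0, float(np.real(j)))
    f_inv_t = np.swapaxes(_inv3(F), -1, -2)
    c = np.swapaxes(F, -1, -2) @ F
    jm23 = j ** (-2.0 / 3.0)
    i1 = np.trace(c)
    i4 = a0 @ c @ a0
    i1b, i4b = jm23 * i1, jm23 * i4
    psi4 = _fibre_dpsi(i4b, tis)
    fa = F @ a0
    p = (tis.kappa * (j - 1.0) * j * f_inv_t
         + tis.mu_p * jm23 * (F - (i1 / 3.0) * f_inv_t)
         + 2.0 * psi4 * jm23 * (np.outer(fa, a0) - (i4 / 3.0) * f_inv_t))
    if active is not None:
        # CU stress acts along the fibre with the geometric stretch |F a0|
        p = p + 2.0 * _active_dpsi(i4, *active) * np.outer(fa, a0)
    return p


# --- assembled system ---------------------------------------------------------

class FESystem:
    """Assembled Q1/P0 hyperelastic system on a hexahedral mesh.

    Parameters
    ----------
    nodes : (nn, 3) reference coordinates (mm)
    elements : (nel, 8) connectivity (positively oriented hexes)
    tissue : TissueParams
    fibre : (nel, 8, 3) unit fibre directions per Gauss point
    """

    def __init__(self, nodes, elements, tissue: TissueParams, fibre):
        self.nodes = np.asarray(nodes, dtype=float)
        self.elements = np.asarray(elements, dtype=int)
        self.tissue = tissue
        nel = self.elements.shape[0]
        self.fibre = np.broadcast_to(np.asarray(fibre, dtype=float),
                                     (nel, N_GP, 3)).copy()
        norms = np.linalg.norm(self.fibre, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("fibre directions must be unit vectors")
        xe = self.nodes[self.elements]                       # (nel, 8, 3)
        j0 = np.einsum("eai,qaj->eqij", xe, _DNDXI)          # (nel, ngp, 3, 3)
        det0 = _det3(j0)
        if np.any(det0 <= 0):
            e = int(np.argwhere(det0 <= 0)[0][0])
            raise ElementInversionError(e, float(det0.min()))
        self.grad = np.einsum("qaj,eqjk->eqak", _DNDXI, _inv3(j0))
        self.wdet = det0                                     # unit gauss weights
        self.vol0 = self.wdet.sum(axis=1)
        self.n_nodes = self.nodes.shape[0]
        self.n_dof = 3 * self.n_nodes
        self._fixed_dofs = np.zeros(0, dtype=int)
        self._fixed_vals = np.zeros(0)
        self._free_mask = np.ones(self.n_dof, dtype=bool)
        dofmap = (3 * self.elements[:, :, None] + np.arange(3)[None, None, :])
        self.dofmap = dofmap.reshape(nel, 24)

    # -- boundary conditions --

    def set_dirichlet(self, bcs: dict[tuple[int, int], float]) -> None:
        """Prescribe displacement components: {(node, component): value}."""
        if not bcs:
            self._fixed_dofs = np.zeros(0, dtype=int)
            self._fixed_vals = np.zeros(0)
        else:
            items = sorted((3 * n + c, v) for (n, c), v in bcs.items())
            self._fixed_dofs = np.array([d for d, _ in items], dtype=int)
            self._fixed_vals = np.array([v for _, v in items], dtype=float)
        self._free_mask = np.ones(self.n_dof, dtype=bool)
        self._free_mask[self._fixed_dofs] = False

    def apply_bcs(self, u: np.ndarray) -> np.ndarray:
        out = np.array(u, dtype=float).reshape(self.n_dof)
        out[self._fixed_dofs] = self._fixed_vals
        return out.reshape(self.n_nodes, 3)

    # -- kinematics and forces --

    def _deformation(self, u):
        ue = u.reshape(self.n_nodes, 3)[self.elements]       # (nel, 8, 3)
        f = np.einsum("eai,eqaj->eqij", ue, self.grad)
        f = f + np.eye(3, dtype=f.dtype)
        j = _det3(f)
        if np.any(np.real(j) <= 0):
            e = int(np.argwhere(np.real(j) <= 0)[0][0])
            raise ElementInversionError(e, float(np.real(j).min()))
        jbar = (self.wdet * j).sum(axis=1) / self.vol0        # element mean
        return f, j, jbar

    def kinematics(self, u):
        """Per-Gauss-point deformation measures for a displacement field."""
        f, j, jbar = self._deformation(np.asarray(u, dtype=float))
        c = np.einsum("eqki,eqkj->eqij", f, f)
        jm23 = j ** (-2.0 / 3.0)
        i1b = jm23 * np.trace(c, axis1=-2, axis2=-1)
        i4 = np.einsum("eqi,eqij,eqj->eq", self.fibre, c, self.fibre)
        i4b = jm23 * i4
        # "lam" is the geometric fibre stretch |F a0| fed to the CU model
        return {"F": f, "J": j, "J_bar": jbar, "I1_bar": i1b, "I4_bar": i4b,
                "I4": i4, "lam": np.sqrt(i4)}

    def energy(self, u, active=None) -> float:
        """Total strain energy (kPa mm^3 = uJ)."""
        f, j, jbar = self._deformation(np.asarray(u))
        c = np.einsum("eqki,eqkj->eqij", f, f)
        jm23 = j ** (-2.0 / 3.0)
        i1b = jm23 * np.trace(c, axis1=-2, axis2=-1)
        i4b = jm23 * np.einsum("eqi,eqij,eqj->eq", self.fibre, c, self.fibre)
        tis = self.tissue
        q = tis.c_p2 * (i4b - 1.0) ** 2
        if np.any(np.real(q) > _EXP_GUARD):
            raise FloatingPointError("fibre exponential overflow")
        psi = 0.5 * tis.mu_p * (i1b - 3.0) + tis.c_p1 / (2 * tis.c_p2) * (np.exp(q) - 1)
        if active is not None:
            k_act, u_fs = active
            i4 = np.einsum("eqi,eqij,eqj->eq", self.fibre, c, self.fibre)
            lam = np.sqrt(i4)
            psi = psi + 0.5 * k_act * (lam - 1.0 - u_fs) ** 2
        e_iso = (self.wdet * psi).sum()
        e_vol = (self.vol0 * 0.5 * tis.kappa * (jbar - 1.0) ** 2).sum()
        return complex(e_iso + e_vol) if np.iscomplexobj(u) else float(e_iso + e_vol)

    def internal_force(self, u, active=None):
        """Assembled internal nodal forces dE/du, shape (nn, 3); complex-safe."""
        u = np.asarray(u)
        f, j, jbar = self._deformation(u)
        finv_t = np.swapaxes(_inv3(f), -1, -2)
        c = np.einsum("eqki,eqkj->eqij", f, f)
        jm23 = j ** (-2.0 / 3.0)
        i1 = np.trace(c, axis1=-2, axis2=-1)
        i4 = np.einsum("eqi,eqij,eqj->eq", self.fibre, c, self.fibre)
        i4b = jm23 * i4
        tis = self.tissue
        psi4 = _fibre_dpsi(i4b, tis)
        fa = np.einsum("eqij,eqj->eqi", f, self.fibre)
        p = (tis.mu_p * jm23[..., None, None] * (f - (i1 / 3.0)[..., None, None] * finv_t)
             + 2.0 * (psi4 * jm23)[..., None, None]
             * (np.einsum("eqi,eqj->eqij", fa, self.fibre)
                - (i4 / 3.0)[..., None, None] * finv_t)
             + (tis.kappa * (jbar - 1.0))[:, None, None, None]
             * j[..., None, None] * finv_t)
        if active is not None:
            k_act, u_fs = active
            p = p + 2.0 * _active_dpsi(i4, k_act, u_fs)[..., None, None] \
                * np.einsum("eqi,eqj->eqij", fa, self.fibre)
        fe = np.einsum("eq,eqij,eqaj->eai", self.wdet, p, self.grad)
        out = np.zeros((self.n_nodes, 3), dtype=fe.dtype)
        np.add.at(out, self.elements, fe)
        return out

    def element_pressures(self, u) -> np.ndarray:
        _, _, jbar = self._deformation(np.asarray(u, dtype=float))
        return self.tissue.kappa * (jbar - 1.0)

    # -- tangent and Newton ----------------------------------------------------

    def tangent(self, u, active=None) -> sp.csr_matrix:
        """Consistent tangent d f_int / d u by complex-step differentiation.

        Perturbations act in local element space (one of the 24 element dofs
        at a time, across all elements simultaneously), so shared nodes are
        handled correctly by the scatter-add assembly.
        """
        u = np.asarray(u, dtype=float).reshape(self.n_nodes, 3)
        nel = self.elements.shape[0]
        ke = np.empty((nel, 24, 24))
        ue = u[self.elements].reshape(nel, 24)
        for d in range(24):
            ue_c = ue.astype(complex)
            ue_c[:, d] += 1j * _CS_H
            ke[:, :, d] = self._element_forces_local(ue_c, active).imag / _CS_H
        rows = np.repeat(self.dofmap, 24, axis=1).ravel()
        cols = np.tile(self.dofmap, (1, 24)).ravel()
        k = sp.coo_matrix((ke.ravel(), (rows, cols)),
                          shape=(self.n_dof, self.n_dof)).tocsr()
        return k

    def _element_forces_local(self, ue_flat, active):
        """Element forces from per-element displacement vectors (nel, 24)."""
        ue = ue_flat.reshape(-1, 8, 3)
        f = np.einsum("eai,eqaj->eqij", ue, self.grad)
        f = f + np.eye(3, dtype=f.dtype)
        j = _det3(f)
        if np.any(np.real(j) <= 0):
            e = int(np.argwhere(np.real(j) <= 0)[0][0])
            raise ElementInversionError(e, float(np.real(j).min()))
        jbar = (self.wdet * j).sum(axis=1) / self.vol0
        finv_t = np.swapaxes(_inv3(f), -1, -2)
        c = np.einsum("eqki,eqkj->eqij", f, f)
        jm23 = j ** (-2.0 / 3.0)
        i1 = np.trace(c, axis1=-2, axis2=-1)
        i4 = np.einsum("eqi,eqij,eqj->eq", self.fibre, c, self.fibre)
        i4b = jm23 * i4
        tis = self.tissue
        psi4 = _fibre_dpsi(i4b, tis)
        fa = np.einsum("eqij,eqj->eqi", f, self.fibre)
        p = (tis.mu_p * jm23[..., None, None] * (f - (i1 / 3.0)[..., None, None] * finv_t)
             + 2.0 * (psi4 * jm23)[..., None, None]
             * (np.einsum("eqi,eqj->eqij", fa, self.fibre)
                - (i4 / 3.0)[..., None, None] * finv_t)
             + (tis.kappa * (jbar - 1.0))[:, None, None, None]
             * j[..., None, None] * finv_t)
        if active is not None:
            k_act, u_fs = active
            p = p + 2.0 * _active_dpsi(i4, k_act, u_fs)[..., None, None] \
                * np.einsum("eqi,eqj->eqij", fa, self.fibre)
        fe = np.einsum("eq,eqij,eqaj->eai", self.wdet, p, self.grad)
        return fe.reshape(-1, 24)

    def assemble(self, u, active=None):
        """Global residual (free dofs) and tangent (free-free block)."""
        u = self.apply_bcs(u)
        r = self.internal_force(u, active).reshape(self.n_dof)
        k = self.tangent(u, active)
        free = self._free_mask
        return r[free], k[free][:, free]

    def newton_solve(self, u0, active=None, rtol: float = 1e-8,
                     atol: float = 1e-10, max_iter: int = 60,
                     line_search: bool = True) -> FESolution:
        """Newton-Raphson iteration at fixed boundary conditions."""
        u = self.apply_bcs(np.asarray(u0, dtype=float))
        free = self._free_mask
        history = []
        r_norm = np.inf
        for it in range(1, max_iter + 1):
            try:
                fint = self.internal_force(u, active).reshape(self.n_dof)
            except (ElementInversionError, FloatingPointError) as exc:
                # can only happen on the initial guess (BC jump): back off
                raise NewtonError(f"initial state invalid: {exc}", history) from exc
            r = fint[free]
            r_norm = float(np.linalg.norm(r))
            history.append(r_norm)
            ref = max(float(np.linalg.norm(fint)), 1.0)
            if r_norm <= rtol * ref + atol:
                return FESolution(u=u, pressure=self.element_pressures(u),
                                  converged=True, residual_norm=r_norm,
                                  iterations=it, residual_history=history)
            k = self.tangent(u, active)[free][:, free]
            diag_scale = float(np.abs(k.diagonal()).mean())
            accepted = False
            # plain Newton first; on line-search failure retry with Levenberg
            # damping (handles indefinite tangents at local snap-throughs)
            for damp in (0.0, 1e-6, 1e-4, 1e-2, 1e-1, 1.0, 10.0):
                kd = k if damp == 0.0 else \
                    k + damp * diag_scale * sp.identity(k.shape[0], format="csr")
                du = spla.spsolve(kd.tocsc(), -r)
                if not np.all(np.isfinite(du)):
                    if damp == 0.0:
                        continue     # singular plain tangent: go damped
                    raise NewtonError("singular constrained system "
                                      "(check boundary conditions)", history)
                step = 1.0
                for _ in range(8):
                    u_try = u.copy().reshape(self.n_dof)
                    u_try[free] += step * du
                    u_try = u_try.reshape(self.n_nodes, 3)
                    try:
                        r_try = self.internal_force(u_try, active) \
                            .reshape(self.n_dof)[free]
                    except (ElementInversionError, FloatingPointError):
                        step *= 0.5
                        continue
                    if not line_search or np.linalg.norm(r_try) < max(r_norm, atol):
                        u = u_try
                        accepted = True
                        break
                    step *= 0.5
                if accepted:
                    break
            if not accepted:
                raise NewtonError(f"line search failed at iteration {it}", history)
        raise NewtonError(f"Newton did not converge in {max_iter} iterations "
                          f"(residual {r_norm:.3e})", history)


def hook_force(system: FESystem, sol: FESolution, hook_nodes,
               direction: int = 0, symmetry_factor: float = 4.0,
               active=None) -> float:
    """Hook reaction force (mN): sum of internal forces at the hook node set.

    The one-eighth ring models a quarter of the circumference and half of the
    axial width of one hook contact, hence the default symmetry factor 4.
    """
    hook_nodes = np.asarray(hook_nodes, dtype=int)
    if hook_nodes.size == 0:
        raise ValueError("empty hook contact node set")
    f = system.internal_force(sol.u, active)
    return symmetry_factor * float(f[hook_nodes, direction].sum())


def loading_phase(system: FESystem, hook_nodes, base_bcs: dict,
                  target_mN: float, symmetry_factor: float = 4.0,
                  rel_tol: float = 0.005, d_init: float = 0.05,
                  d_max: float = 2.0, max_iter: int = 40):
    """Displacement-controlled calibration of the hook separation to a preload.

    Secant iteration on the prescribed hook displacement d (applied along x
    to every hook-contact node) until the passive hook force matches
    ``target_mN`` within ``rel_tol``.  Load steps are sub-incremented when
    Newton fails.  Returns ``(solution, d, force)``.
    """
    if target_mN == 0.0:
        sol = _solve_at(system, hook_nodes, base_bcs, 0.0, None)
        return sol, 0.0, 0.0

    cache_u = {0.0: np.zeros((system.n_nodes, 3))}
    state = {"dd": d_init / 4}   # adaptive continuation increment

    def eval_at(d):
        start = max(x for x in cache_u if x <= d + 1e-15)
        u_cur, cur, sol = cache_u[start], start, None
        # adaptive incremental continuation from the nearest solved state below d
        while cur < d - 1e-15:
            dd = min(state["dd"], d - cur)
            try:
                sol = _solve_at(system, hook_nodes, base_bcs, cur + dd, u_cur)
            except NewtonError:
                state["dd"] = dd / 2
                if state["dd"] < d_init / 1024:
                    raise
                continue
            cur += dd
            u_cur = sol.u
            cache_u[cur] = sol.u
            if sol.iterations <= 8:
                state["dd"] = min(1.5 * state["dd"], d_init)
        if sol is None:
            sol = _solve_at(system, hook_nodes, base_bcs, d, u_cur)
        f = hook_force(system, sol, hook_nodes, symmetry_factor=symmetry_factor)
        return sol, f

    # march outward until the target force is passed (passive response stiffens)
    d0, f0 = 0.0, 0.0
    d1 = d_init
    sol, f1 = eval_at(d1)
    while f1 < target_mN:
        d0, f0 = d1, f1
        d1 = min(1.5 * d1, d_max)
        if d1 <= d0 + 1e-12:
            raise NewtonError(f"preload {target_mN} mN unreachable below d_max={d_max}")
        sol, f1 = eval_at(d1)
    # secant refinement with bisection fallback inside the bracket [d0, d1]
    for _ in range(max_iter):
        if abs(f1 - target_mN) <= rel_tol * abs(target_mN):
            return sol, d1, f1
        denom = f1 - f0
        d_new = d1 - (f1 - target_mN) * (d1 - d0) / denom if denom != 0 else 0.5 * (d0 + d1)
        if not (min(d0, d1) < d_new < max(d0, d1)):
            d_new = 0.5 * (d0 + d1)
        sol_new, f_new = eval_at(d_new)
        if (f_new - target_mN) * (f1 - target_mN) < 0:
            d0, f0 = d1, f1
        d1, f1, sol = d_new, f_new, sol_new
    raise NewtonError(f"loading phase did not converge to {target_mN} mN "
                      f"(last force {f1:.4g} mN)")


def _solve_at(system: FESystem, hook_nodes, base_bcs, d, u0):
    bcs = dict(base_bcs)
    for n in hook_nodes:
        bcs[(int(n), 0)] = d
    system.set_dirichlet(bcs)
    if u0 is None:
        u0 = np.zeros((system.n_nodes, 3))
    return system.newton_solve(u0)
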
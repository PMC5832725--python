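"""Chemo-mechanical contractile-unit (CU) model evaluated at Gauss points.

A contractile unit is an averaged actin-myosin filament assembly.  Its
internal variable u_fs is the relative filament sliding, normalised to the
reference CU length and negative in contraction.  It splits into a chemical
component u_fs_c (driven by the myosin power stroke through a force balance)
and a mechanical component u_fs_m (eliminated here: external deformation
enters through the CU stretch lam in the elastic-elongation relation, so
u_fs_m stays identically zero).

Attached cross-bridges act as elastic springs of equal stiffness; their
average elastic elongation is

    u_e_bar = lam - 1 - u_fs.

The filament-resistance stress (also the CU-averaged first Piola-Kirchhoff
stress) is

    P_a = mu_a * L_fo(u_fs) * (n_AMp + n_AM) * u_e_bar,

with the parabolic relative filament-overlap function

    L_fo(u_fs) = max(0, 1 - s_overlap * (u_fs + u_opt)^2),

whose vertex sits at u_fs = -u_opt: sliding in the contraction direction
moves the filaments towards optimal overlap.  The chemical sliding evolves
by the stick-slip force balance between P_a and the cycling driving stress

    P_c = kappa_AMp * n_AMp                     (contraction branch)
    P_c = kappa_AMp * n_AMp + kappa_AM * n_AM   (extension branch),

the latch bridges bearing force only against extension.  The active free
energy fed to the continuum is

    Psi_a = mu_a/2 * L_fo * (n_AMp + n_AM) * u_e_bar^2,   lam = sqrt(I4),

differentiated analytically with respect to the fourth invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CUParams",
    "CUState",
    "elastic_elongation",
    "overlap",
    "driving_stress",
    "filament_stress",
    "active_energy",
    "active_energy_derivs",
    "evolve_ufs_c",
    "sliding_rate",
]

CONTRACTION = "contraction"
EXTENSION = "extension"


@dataclass
class CUParams:
    """Contractile-unit material parameters (defaults: reference set)."""

    alpha_a: float = 26.68       # sliding-resistance scale (kPa)
    beta_a: float = 0.00833      # sliding mobility rate (1/s)
    kappa_AMp: float = 203.71    # power-stroke force of a cycling CB (kPa)
    kappa_AM: float = 61.14      # force-bearing capacity of a latch CB (kPa)
    u_opt: float = 0.48          # sliding offset of optimal filament overlap (-)
    s_overlap: float = 0.4255    # curvature of the overlap parabola (-)
    mu_a: float = 5301.0         # active shear modulus (kPa)

    def __post_init__(self):
        for name in ("alpha_a", "beta_a", "kappa_AMp", "kappa_AM",
                     "u_opt", "s_overlap", "mu_a"):
            if getattr(self, name) < 0:
                raise ValueError(f"CU parameter {name} must be positive")


@dataclass
class CUState:
    """State of one contractile unit at one Gauss point."""

    u_fs_c: float = 0.0   # chemical sliding component (-)
    u_fs_m: float = 0.0   # mechanical sliding component (-, kept at 0)
    lam: float = 1.0      # CU stretch of the previous continuum step (-)
    u_e_bar: float = 0.0  # average elastic CB elongation (-)
    P_c: float = 0.0      # driving stress (kPa)
    P_a: float = 0.0      # filament-resistance 1st Piola-Kirchhoff stress (kPa)

    @property
    def u_fs(self) -> float:
        return self.u_fs_c + self.u_fs_m


def elastic_elongation(lam, u_fs):
    """Average elastic elongation of attached cross-bridges: lam - 1 - u_fs."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam.real <= 0):
        raise ValueError("CU stretch lam must be positive")
    val = lam - 1.0 - u_fs
    return float(val) if val.ndim == 0 else val


def overlap(u_fs, p: CUParams):
    """Relative filament overlap: a downward parabola in u_fs, clamped at 0."""
    val = 1.0 - p.s_overlap * (np.asarray(u_fs) + p.u_opt) ** 2
    val = np.maximum(val, 0.0)
    return float(val) if np.ndim(val) == 0 else val


def driving_stress(n_AMp, n_AM, regime: str, p: CUParams):
    """Cross-bridge driving stress P_c (kPa) for the given sliding regime."""
    if regime == CONTRACTION:
        return p.kappa_AMp * n_AMp
    if regime == EXTENSION:
        return p.kappa_AMp * n_AMp + p.kappa_AM * n_AM
    raise ValueError(f"unknown regime {regime!r}")


def filament_stress(lam, u_fs, n_AMp, n_AM, p: CUParams):
    """Filament-sliding resistance P_a = mu_a * L_fo * (n_AMp + n_AM) * u_e_bar."""
    return p.mu_a * overlap(u_fs, p) * (n_AMp + n_AM) * elastic_elongation(lam, u_fs)


def sliding_rate(lam, u_fs, n_AMp, n_AM, p: CUParams):
    """du_fs_c/dt from the stick-slip force balance (vectorised).

    Contraction when the cycling drive exceeds the elastic resistance,
    extension when the resistance exceeds drive plus latch capacity, and a
    stuck (zero-rate) band in between.  The rate is continuous across both
    thresholds.
    """
    p_a = filament_stress(lam, u_fs, n_AMp, n_AM, p)
    p_con = p.kappa_AMp * np.asarray(n_AMp)
    p_ext = p_con + p.kappa_AM * np.asarray(n_AM)
    mob = p.beta_a / p.alpha_a
    rate = np.where(p_a < p_con, mob * (p_a - p_con),
                    np.where(p_a > p_ext, mob * (p_a - p_ext), 0.0))
    return (float(rate), float(p_a)) if np.ndim(rate) == 0 else (rate, p_a)


def evolve_ufs_c(state: CUState, n_AMp: float, n_AM: float, dt: float,
                 p: CUParams, lam: float | None = None) -> CUState:
    """Forward-Euler update of the chemical sliding component.

    ``lam`` is the CU stretch of the *previous* continuum step (lagged
    coupling); if omitted the stretch stored in the state is reused.
    A guard rejects updates whose sliding increment exceeds 0.2 (instability).
    """
    lam = state.lam if lam is None else lam
    rate, p_a = sliding_rate(lam, state.u_fs_c + state.u_fs_m, n_AMp, n_AM, p)
    du = dt * rate
    if abs(du) > 0.2:
        raise ValueError(f"sliding increment {du:.3g} too large; reduce dt")
    u_c = state.u_fs_c + du
    u_fs = u_c + state.u_fs_m
    regime = CONTRACTION if rate < 0 else EXTENSION
    return CUState(
        u_fs_c=u_c, u_fs_m=state.u_fs_m, lam=lam,
        u_e_bar=elastic_elongation(lam, u_fs),
        P_c=driving_stress(n_AMp, n_AM, regime, p),
        P_a=filament_stress(lam, u_fs, n_AMp, n_AM, p),
    )


def active_energy(i4, u_fs, n_att, p: CUParams):
    """Active free energy Psi_a(I4) at frozen sliding u_fs and attached fraction."""
    i4 = np.asarray(i4, dtype=float)
    if np.any(i4 <= 0):
        raise ValueError("fourth invariant I4 must be positive")
    lam = np.sqrt(i4)
    ue = lam - 1.0 - np.asarray(u_fs)
    val = 0.5 * p.mu_a * overlap(u_fs, p) * np.asarray(n_att) * ue ** 2
    return float(val) if val.ndim == 0 else val


def active_energy_derivs(i4, u_fs, n_att, p: CUParams):
    """Analytic (dPsi_a/dI4, d2Psi_a/dI4^2), chain-ruled through lam = sqrt(I4).

    With k = mu_a * L_fo * n_att and u_e_bar = lam - 1 - u_fs:
        dPsi/dI4   = k * u_e_bar / (2 lam)
        d2Psi/dI4^2 = k / (4 I4) - k * u_e_bar / (4 lam^3)
    """
    i4 = np.asarray(i4, dtype=float)
    if np.any(i4 <= 0):
        raise ValueError("fourth invariant I4 must be positive")
    lam = np.sqrt(i4)
    k = p.mu_a * overlap(u_fs, p) * np.asarray(n_att)
    ue = lam - 1.0 - np.asarray(u_fs)
    d1 = k * ue / (2.0 * lam)
    d2 = k / (4.0 * i4) - k * ue / (4.0 * lam ** 3)
    if np.ndim(d1) == 0:
        return float(d1), float(d2)
    return d1, d2
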
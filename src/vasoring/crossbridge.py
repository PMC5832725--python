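"""Four-state actin-myosin cross-bridge kinetics (Hai-Murphy type).

States are the fractions of myosin heads that are detached/dephosphorylated
(n_M), detached/phosphorylated (n_Mp), attached/phosphorylated (n_AMp) and
attached/dephosphorylated latch bridges (n_AM).  The fractions sum to one;
n_M is eliminated algebraically so conservation is structural, not numerical.

The transition graph is declared as an edge list so it can be audited:

    M   --tau1--> Mp      phosphorylation (Ca2+-driven, via tau1(chi))
    Mp  --tau2--> M       dephosphorylation
    Mp  --tau3--> AMp     attachment
    AMp --tau4--> Mp      detachment
    AMp --tau2--> AM      dephosphorylation of an attached bridge
    AM  --tau1--> AMp     re-phosphorylation of a latch bridge
    AM  --tau5--> M       latch-bridge detachment

The phosphorylation rate tau1 is a saturating (Hill) function of cytosolic
Ca2+ scaled by tau_0 and by the enhancement coefficient theta; all other
rates are constants.  Kinetics are advanced by forward Euler at the cellular
time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CBParams",
    "CBState",
    "RATE_EDGES",
    "STATE_NAMES",
    "tau1",
    "rate_matrix",
    "cb_rhs",
    "step_cb",
    "steady_state",
    "attached_fraction",
]

STATE_NAMES = ("M", "Mp", "AMp", "AM")

#: (source state, destination state, rate name) -- the auditable graph.
RATE_EDGES = (
    ("M", "Mp", "tau1"),
    ("Mp", "M", "tau2"),
    ("Mp", "AMp", "tau3"),
    ("AMp", "Mp", "tau4"),
    ("AMp", "AM", "tau2"),
    ("AM", "AMp", "tau1"),
    ("AM", "M", "tau5"),
)


@dataclass
class CBParams:
    """Cross-bridge kinetic constants (defaults: reference parameter set)."""

    tau_0: float = 1.7    # phosphorylation scale (1/s)
    tau_2: float = 0.5    # dephosphorylation rate (1/s)
    tau_3: float = 0.4    # attachment rate (1/s)
    tau_4: float = 0.1    # detachment rate (1/s)
    tau_5: float = 1.0    # latch-bridge detachment rate (1/s)
    chi_0: float = 0.6    # Ca2+ saturation constant (uM)
    theta: float = 1.0    # enhancement kinetics coefficient (-)

    def max_rate(self, chi_max: float = 2.0) -> float:
        return max(tau1(chi_max, self), self.tau_2, self.tau_3, self.tau_4, self.tau_5)


@dataclass
class CBState:
    """Cross-bridge state; n_M is implicit (1 - n_Mp - n_AMp - n_AM)."""

    n_Mp: float = 0.5
    n_AMp: float = 0.0
    n_AM: float = 0.0

    @property
    def n_M(self) -> float:
        return 1.0 - self.n_Mp - self.n_AMp - self.n_AM

    def as_array(self) -> np.ndarray:
        """Independent coordinates (n_Mp, n_AMp, n_AM)."""
        return np.array([self.n_Mp, self.n_AMp, self.n_AM], dtype=float)

    def full(self) -> np.ndarray:
        """All four fractions (n_M, n_Mp, n_AMp, n_AM)."""
        return np.array([self.n_M, self.n_Mp, self.n_AMp, self.n_AM], dtype=float)

    def validate(self, tol: float = 1e-9) -> None:
        f = self.full()
        if np.any(f < -tol) or np.any(f > 1 + tol):
            raise ValueError(f"cross-bridge fraction out of [0,1]: {f} "
                             "(time step too large?)")


def tau1(chi, p: CBParams):
    """Ca2+-dependent phosphorylation rate (1/s).

    tau1 = theta * tau_0 * chi^2 / (chi^2 + chi_0^2): zero without Ca2+,
    saturating at theta*tau_0, half-maximal at chi = chi_0.
    """
    chi = np.asarray(chi, dtype=float)
    if np.any(chi < 0):
        raise ValueError("chi must be >= 0")
    val = p.theta * p.tau_0 * chi ** 2 / (chi ** 2 + p.chi_0 ** 2)
    return float(val) if val.ndim == 0 else val


def rate_matrix(tau1_val: float, p: CBParams) -> np.ndarray:
    """Generator matrix A (4x4) with dn/dt = A @ n, built from RATE_EDGES."""
    rates = {"tau1": tau1_val, "tau2": p.tau_2, "tau3": p.tau_3,
             "tau4": p.tau_4, "tau5": p.tau_5}
    idx = {name: k for k, name in enumerate(STATE_NAMES)}
    A = np.zeros((4, 4))
    for src, dst, rname in RATE_EDGES:
        r = rates[rname]
        A[idx[dst], idx[src]] += r
        A[idx[src], idx[src]] -= r
    return A


def cb_rhs(s: CBState, tau1_val: float, p: CBParams) -> np.ndarray:
    """Time derivatives of all four fractions (sum exactly zero)."""
    return rate_matrix(tau1_val, p) @ s.full()


def _reduced_system(tau1_val, p: CBParams):
    """3x3 system for y = (n_Mp, n_AMp, n_AM): dy/dt = M y + b (n_M eliminated)."""
    A = rate_matrix(tau1_val, p)
    sub = A[1:, 1:]
    col_m = A[1:, 0]
    # n_M = 1 - sum(y): dy/dt = (sub - col_m 1^T) y + col_m
    M = sub - np.outer(col_m, np.ones(3)) if np.ndim(tau1_val) == 0 else None
    return M, col_m


def step_cb(s: CBState, chi: float, dt_cell: float, p: CBParams) -> CBState:
    """One forward-Euler step of the reduced (3-variable) kinetics.

    Conservation holds by construction; a guard rejects steps that push any
    fraction outside [0, 1] by more than 1e-9.
    """
    t1 = tau1(chi, p)
    M, b = _reduced_system(t1, p)
    y = s.as_array()
    y_new = y + dt_cell * (M @ y + b)
    out = CBState(*y_new)
    out.validate()
    return out


def step_cb_arrays(n_Mp, n_AMp, n_AM, chi, dt_cell, p: CBParams):
    """Vectorised forward-Euler step over arrays of cells.

    Returns updated (n_Mp, n_AMp, n_AM); same guard as :func:`step_cb`.
    """
    t1 = p.theta * p.tau_0 * chi ** 2 / (chi ** 2 + p.chi_0 ** 2)
    n_M = 1.0 - n_Mp - n_AMp - n_AM
    d_Mp = t1 * n_M - (p.tau_2 + p.tau_3) * n_Mp + p.tau_4 * n_AMp
    d_AMp = p.tau_3 * n_Mp - (p.tau_4 + p.tau_2) * n_AMp + t1 * n_AM
    d_AM = p.tau_2 * n_AMp - (t1 + p.tau_5) * n_AM
    out = (n_Mp + dt_cell * d_Mp, n_AMp + dt_cell * d_AMp, n_AM + dt_cell * d_AM)
    lo = min(float(np.min(o)) for o in out)
    hi = float(np.max(out[0] + out[1] + out[2]))
    if lo < -1e-9 or hi > 1 + 1e-9:
        raise ValueError("cross-bridge fraction left [0,1]; reduce dt_cell")
    return out


def steady_state(tau1_val: float, p: CBParams) -> np.ndarray:
    """Stationary fractions at constant chi: nullspace of the rate matrix.

    Solved from the reduced affine system M y = -b (unique for positive rates).
    """
    M, b = _reduced_system(tau1_val, p)
    y = np.linalg.solve(M, -b)
    return np.array([1.0 - y.sum(), *y])


def attached_fraction(s: CBState) -> float:
    """Local force proxy: the attached fraction n_AMp + n_AM."""
    return s.n_AMp + s.n_AM
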
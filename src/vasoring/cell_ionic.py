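"""Ionic Ca2+ dynamics of vascular smooth muscle cells and their gap-junction network.

Each smooth muscle cell (SMC) is described by three state variables:

* ``chi``  -- cytosolic Ca2+ concentration (uM)
* ``zeta`` -- sarcoplasmic-reticulum (SR) Ca2+ concentration (uM)
* ``eta``  -- membrane potential (V)

The cytosolic balance combines four extracellular influx pathways (constant
non-selective cation channels NSCC, store-operated channels SOCC,
voltage-operated channels VOCC and reverse-mode Na+/Ca2+ exchange NCX), the
SR store cycle (SERCA uptake, ryanodine-receptor Ca2+-induced Ca2+ release,
passive leak) and ATPase extrusion across the plasma membrane.  The membrane
potential relaxes under the charge carried by the VOCC, NCX, Cl- and K+
fluxes.  Neighbouring cells exchange Ca2+ and voltage through linear
gap-junction currents.

Units follow the parameter table verbatim (uM, V, s); there is no internal
unit conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "CellParams",
    "CellState",
    "FluxVector",
    "CellNetwork",
    "DEFAULT_INITIAL_STATE",
    "extracellular_influx",
    "store_exchange",
    "membrane_efflux",
    "all_fluxes",
    "coupling_currents",
    "coupling_all",
    "cell_rhs",
    "network_rhs",
    "integrate_network",
    "IntegrationError",
    "NegativeConcentrationError",
]

# Default initial state chi (uM), zeta (uM), eta (V).
DEFAULT_INITIAL_STATE = (0.1, 0.2, -0.02)


class IntegrationError(RuntimeError):
    """Adaptive step-size underflow (stiffness) or non-finite state."""

    def __init__(self, message: str, t: float | None = None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class NegativeConcentrationError(IntegrationError):
    """chi or zeta dropped below -1e-9: almost certainly a model/transcription bug."""


@dataclass
class CellParams:
    """Ca2+-dynamics parameters of one SMC (defaults: reference parameter set).

    Fields may be scalars or per-cell numpy arrays (broadcast in network use).
    """

    Phi_A: float = 0.6      # Ca2+ influx via NSCC (uM/s)
    L_SR: float = 0.025     # SR leak rate constant (1/s)
    gamma: float = 1.0      # flux -> membrane-potential scaling (V/uM)
    A_S: float = 0.0        # SOCC rate (uM/s scale; table lists 1/s, see docs)
    zeta_S: float = 4.0     # SOCC half-point in SR load (uM)
    E_Ca: float = 12.0      # VOCC conductance (uM/(V s))
    z_Ca1: float = 0.13     # VOCC reversal potential (V)
    z_Ca2: float = -0.024   # VOCC activation half-point (V)
    R_Ca: float = 0.0085    # VOCC activation slope (V)
    E_NCX: float = 43.8     # NCX conductance (uM/(V s))
    z_NCX: float = -0.04    # NCX reversal potential (V)
    x_NCX: float = 0.5      # NCX Ca2+ half-activation (uM)
    B_SR: float = 400.0     # SERCA uptake rate (uM/s)
    x_SR: float = 4.4       # SERCA half-point (uM)
    n_SR: int = 2           # SERCA Hill coefficient (-)
    C_Ry: float = 1250.0    # RyR CICR rate (uM/s)
    y_Ry: float = 8.9       # CICR half-point in SR load (uM)
    x_Ry: float = 0.9       # CICR half-point in cytosolic Ca2+ (uM)
    m_Ry: int = 2           # CICR Hill coefficient, SR-load sigmoid (-)
    p_Ry: int = 4           # CICR Hill coefficient, cytosolic sigmoid (-)
    D_EX: float = 6.25      # ATPase extrusion rate (uM/s)
    z_Ex: float = -0.1      # extrusion voltage offset (V)
    R_Ex: float = 0.25      # extrusion voltage scale (V)
    k_Ex: int = 2           # extrusion Ca2+ exponent (-)
    E_Cl: float = 65.0      # Cl- conductance (uM/(V s))
    z_Cl: float = -0.025    # Cl- reversal potential (V)
    x_Cl: float = 0.0       # Cl- channel Ca2+ sensitivity (uM; 0 = insensitive)
    E_K: float = 43.0       # K+ conductance (uM/(V s))
    z_K: float = -0.095     # K+ reversal potential (V)
    z_Ca3: float = -0.027   # K_Ca activation half-point (V)
    R_K: float = 0.012      # K_Ca activation slope (V)
    beta_K: float = 0.0     # K_Ca channel Ca2+ sensitivity (uM; 0 = insensitive)
    alpha_C: float = 1.0    # intercellular Ca2+ diffusivity (1/s)
    alpha_V: float = 1.0    # intercellular voltage diffusivity (1/s)

    def copy(self) -> "CellParams":
        return replace(self)

    def validate(self) -> None:
        for f in fields(self):
            v = np.asarray(getattr(self, f.name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite parameter {f.name}")
        for name in ("L_SR", "A_S", "E_Ca", "E_NCX", "B_SR", "C_Ry",
                     "D_EX", "E_Cl", "E_K", "alpha_C", "alpha_V"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"rate/conductance {name} must be >= 0")
        for name in ("n_SR", "m_Ry", "p_Ry"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ValueError(f"Hill exponent {name} must be a positive integer")


@dataclass
class CellState:
    """State of one SMC."""

    chi: float = DEFAULT_INITIAL_STATE[0]
    zeta: float = DEFAULT_INITIAL_STATE[1]
    eta: float = DEFAULT_INITIAL_STATE[2]

    def as_array(self) -> np.ndarray:
        return np.array([self.chi, self.zeta, self.eta], dtype=float)

    def validate(self) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise IntegrationError("non-finite cell state", state=self)
        if self.chi < 0 or self.zeta < 0:
            raise NegativeConcentrationError(
                f"negative concentration chi={self.chi}, zeta={self.zeta}", state=self)


class FluxVector(NamedTuple):
    """All ten concentration currents of one cell (uM/s)."""

    Phi_A: float
    Phi_S: float
    Phi_V: float
    Phi_N: float
    Phi_B: float
    Phi_C: float
    Phi_L: float
    Phi_D: float
    Phi_Cl: float
    Phi_K: float


def _check_state_arrays(chi, zeta, eta):
    if not (np.all(np.isfinite(chi)) and np.all(np.isfinite(zeta)) and np.all(np.isfinite(eta))):
        raise IntegrationError("non-finite state passed to flux evaluation")


def _ca_gate(chi, half):
    """Saturating Ca2+ gating factor chi/(chi+half); identically 1 when half == 0."""
    if np.all(np.asarray(half) == 0.0):
        return np.ones_like(np.asarray(chi, dtype=float))
    return chi / (chi + half)


def extracellular_influx(state: CellState, p: CellParams):
    """Membrane Ca2+ influx pathways (Phi_A, Phi_S, Phi_V, Phi_N), all in uM/s.

    Phi_A (NSCC) is the constant parameter.  Phi_S (SOCC) is an inhibitory
    Hill function of the SR load.  Phi_V (VOCC) combines the driving force
    towards the Ca2+ reversal potential with a sigmoidal voltage activation.
    Phi_N is the reverse-mode NCX influx: positive when the membrane is
    depolarised beyond the exchanger reversal potential.
    """
    chi, zeta, eta = state.chi, state.zeta, state.eta
    _check_state_arrays(chi, zeta, eta)
    phi_a = np.broadcast_to(np.asarray(p.Phi_A, dtype=float), np.shape(chi)) \
        if np.shape(chi) else float(p.Phi_A)
    phi_s = p.A_S * p.zeta_S ** 2 / (p.zeta_S ** 2 + zeta ** 2)
    act = 1.0 / (1.0 + np.exp(-(eta - p.z_Ca2) / p.R_Ca))
    phi_v = p.E_Ca * (p.z_Ca1 - eta) * act
    phi_n = p.E_NCX * _ca_gate(chi, p.x_NCX) * (eta - p.z_NCX)
    return phi_a, phi_s, phi_v, phi_n


def store_exchange(state: CellState, p: CellParams):
    """SR store fluxes (Phi_B SERCA uptake, Phi_C CICR release, Phi_L leak)."""
    chi, zeta = state.chi, state.zeta
    if np.any(np.asarray(chi) < 0) or np.any(np.asarray(zeta) < 0):
        raise NegativeConcentrationError(
            "negative concentration passed to store_exchange", state=state)
    phi_b = p.B_SR * chi ** p.n_SR / (chi ** p.n_SR + p.x_SR ** p.n_SR)
    phi_c = (p.C_Ry
             * zeta ** p.m_Ry / (zeta ** p.m_Ry + p.y_Ry ** p.m_Ry)
             * chi ** p.p_Ry / (chi ** p.p_Ry + p.x_Ry ** p.p_Ry))
    phi_l = p.L_SR * zeta
    return phi_b, phi_c, phi_l


def membrane_efflux(state: CellState, p: CellParams):
    """Plasma-membrane removal/repolarisation fluxes (Phi_D, Phi_Cl, Phi_K).

    Phi_D is the ATPase extrusion (vanishes at chi=0); Phi_Cl and Phi_K vanish
    at their reversal potentials z_Cl, z_K.  The optional Ca2+ sensitivities
    x_Cl, beta_K gate the channels; at their default of zero the gates are
    fully open.
    """
    chi, zeta, eta = state.chi, state.zeta, state.eta
    _check_state_arrays(chi, zeta, eta)
    phi_d = p.D_EX * chi ** p.k_Ex * (1.0 + (eta - p.z_Ex) / p.R_Ex)
    phi_cl = p.E_Cl * _ca_gate(chi, p.x_Cl) * (eta - p.z_Cl)
    act_k = 1.0 / (1.0 + np.exp(-(eta - p.z_Ca3) / p.R_K))
    phi_k = p.E_K * _ca_gate(chi, p.beta_K) * (eta - p.z_K) * act_k
    return phi_d, phi_cl, phi_k


def all_fluxes(state: CellState, p: CellParams) -> FluxVector:
    """Evaluate every concentration current of one cell."""
    phi_a, phi_s, phi_v, phi_n = extracellular_influx(state, p)
    phi_b, phi_c, phi_l = store_exchange(state, p)
    phi_d, phi_cl, phi_k = membrane_efflux(state, p)
    return FluxVector(phi_a, phi_s, phi_v, phi_n, phi_b, phi_c, phi_l,
                      phi_d, phi_cl, phi_k)


@dataclass
class CellNetwork:
    """A cluster of SMCs with symmetric neighbour lists (gap junctions).

    ``params`` holds one CellParams whose fields may be per-cell arrays of
    length ``n_cells`` (Phi_A is typically randomised per cell).
    """

    n_cells: int
    params: CellParams = field(default_factory=CellParams)
    adjacency: Sequence[Sequence[int]] = field(default_factory=list)
    states: np.ndarray = None  # (n_cells, 3): chi, zeta, eta

    def __post_init__(self):
        if self.states is None:
            self.states = np.tile(np.array(DEFAULT_INITIAL_STATE), (self.n_cells, 1))
        self.states = np.asarray(self.states, dtype=float)
        if not self.adjacency:
            self.adjacency = [[] for _ in range(self.n_cells)]
        self.validate_adjacency()

    def validate_adjacency(self) -> None:
        if len(self.adjacency) != self.n_cells:
            raise ValueError("adjacency length must equal n_cells")
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if not 0 <= j < self.n_cells:
                    raise ValueError(f"dangling neighbour index {j} for cell {i}")
                if j == i:
                    raise ValueError(f"self-loop at cell {i}")
                if i not in self.adjacency[j]:
                    raise ValueError(f"asymmetric adjacency: {i}->{j} but not {j}->{i}")

    def state_of(self, i: int) -> CellState:
        chi, zeta, eta = self.states[i]
        return CellState(chi, zeta, eta)

    def params_of(self, i: int) -> CellParams:
        kw = {}
        for f in fields(CellParams):
            v = getattr(self.params, f.name)
            kw[f.name] = float(np.asarray(v).ravel()[i]) if np.ndim(v) else v
        return CellParams(**kw)


def coupling_currents(i: int, net: CellNetwork,
                      states: np.ndarray | None = None) -> tuple[float, float]:
    """Net gap-junction exchange fluxes (J_Ca, J_V) received by cell ``i``.

    J = alpha * (sum_j s_j - nNeigh * s_i) over the neighbour set; pairwise
    antisymmetric, so the network totals vanish identically for uniform cell
    volumes.
    """
    s = net.states if states is None else states
    nbrs = net.adjacency[i]
    if not nbrs:
        return 0.0, 0.0
    alpha_c = float(np.asarray(net.params.alpha_C).ravel()[i]) \
        if np.ndim(net.params.alpha_C) else net.params.alpha_C
    alpha_v = float(np.asarray(net.params.alpha_V).ravel()[i]) \
        if np.ndim(net.params.alpha_V) else net.params.alpha_V
    chi_n = sum(s[j, 0] for j in nbrs)
    eta_n = sum(s[j, 2] for j in nbrs)
    n = len(nbrs)
    return alpha_c * (chi_n - n * s[i, 0]), alpha_v * (eta_n - n * s[i, 2])


def coupling_all(net: CellNetwork, states: np.ndarray | None = None) -> np.ndarray:
    """Vectorised coupling currents for all cells: array (n_cells, 2)."""
    s = net.states if states is None else states
    out = np.zeros((net.n_cells, 2))
    for i, nbrs in enumerate(net.adjacency):
        if not nbrs:
            continue
        idx = np.fromiter(nbrs, dtype=int)
        n = len(nbrs)
        out[i, 0] = s[idx, 0].sum() - n * s[i, 0]
        out[i, 1] = s[idx, 2].sum() - n * s[i, 2]
    out[:, 0] *= np.asarray(net.params.alpha_C)
    out[:, 1] *= np.asarray(net.params.alpha_V)
    return out


def _rhs_arrays(chi, zeta, eta, p: CellParams, j_ca, j_v):
    """Right-hand side of the three balance equations (vectorised core).

    d chi /dt = Phi_A + Phi_S + Phi_V + Phi_N - Phi_B + Phi_C + Phi_L - Phi_D + J_Ca
    d zeta/dt = Phi_B - Phi_C - Phi_L
    d eta /dt = gamma * (2 Phi_V - Phi_N - Phi_Cl - Phi_K) + J_V

    The membrane balance counts the divalent VOCC charge twice, the outward
    current of the reverse-mode exchanger, and the repolarising Cl-/K+
    currents; gamma converts net ion movement into a potential rate.
    """
    st = CellState(chi, zeta, eta)
    phi_a, phi_s, phi_v, phi_n = extracellular_influx(st, p)
    phi_b, phi_c, phi_l = store_exchange(st, p)
    phi_d, phi_cl, phi_k = membrane_efflux(st, p)
    dchi = phi_a + phi_s + phi_v + phi_n - phi_b + phi_c + phi_l - phi_d + j_ca
    dzeta = phi_b - phi_c - phi_l
    deta = p.gamma * (2.0 * phi_v - phi_n - phi_cl - phi_k) + j_v
    return dchi, dzeta, deta


def cell_rhs(net: CellNetwork, i: int,
             states: np.ndarray | None = None) -> tuple[float, float, float]:
    """Time derivatives (dchi/dt, dzeta/dt, deta/dt) of cell ``i`` in the network."""
    s = net.states if states is None else states
    j_ca, j_v = coupling_currents(i, net, s)
    p = net.params_of(i)
    chi, zeta, eta = s[i]
    return _rhs_arrays(max(chi, 0.0), max(zeta, 0.0), eta, p, j_ca, j_v)


def network_rhs(net: CellNetwork, states: np.ndarray,
                coupling: np.ndarray | None = None) -> np.ndarray:
    """Vectorised RHS for the whole network, (n_cells, 3).

    ``coupling`` may supply frozen gap-junction currents (n_cells, 2); when
    omitted they are evaluated from ``states``.
    """
    if coupling is None:
        coupling = coupling_all(net, states)
    chi = np.maximum(states[:, 0], 0.0)
    zeta = np.maximum(states[:, 1], 0.0)
    eta = states[:, 2]
    dchi, dzeta, deta = _rhs_arrays(chi, zeta, eta, net.params,
                                    coupling[:, 0], coupling[:, 1])
    return np.stack([np.broadcast_to(dchi, chi.shape),
                     np.broadcast_to(dzeta, chi.shape),
                     np.broadcast_to(deta, chi.shape)], axis=1)


# ---------------------------------------------------------------------------
# Adaptive explicit time integration (Runge-Kutta-Merson with PI step control)
# ---------------------------------------------------------------------------

# Merson's 5-stage embedded pair: 4th-order solution with an error estimate.
_MERSON_C = (0.0, 1 / 3, 1 / 3, 1 / 2, 1.0)


def _merson_step(f, t, y, h):
    """One Runge-Kutta-Merson step: returns (y4, error_estimate)."""
    k1 = f(t, y)
    k2 = f(t + h / 3, y + h * k1 / 3)
    k3 = f(t + h / 3, y + h * (k1 + k2) / 6)
    k4 = f(t + h / 2, y + h * (k1 + 3 * k3) / 8)
    k5 = f(t + h, y + h * (k1 - 3 * k3 + 4 * k4) / 2)
    y4 = y + h * (k1 + 4 * k4 + k5) / 6
    err = h * (2 * k1 - 9 * k3 + 8 * k4 - k5) / 30
    return y4, err


def _adaptive_span(f, t0, t1, y, rtol, atol, h_init):
    """Integrate y' = f(t, y) over [t0, t1] adaptively; returns (y(t1), h_last)."""
    t, h = t0, min(h_init, t1 - t0)
    h_min = 1e-14 * max(abs(t1), 1.0)
    err_prev = 1.0
    while t < t1 - 1e-14 * max(abs(t1), 1.0):
        h = min(h, t1 - t)
        y_new, err = _merson_step(f, t, y, h)
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y_new))
        enorm = float(np.sqrt(np.mean((err / scale) ** 2)))
        if not np.isfinite(enorm):
            raise IntegrationError("non-finite error estimate (integration blow-up)",
                                   t=t, state=y)
        if enorm <= 1.0:
            t += h
            y = y_new
            # PI controller (orders: local error ~ h^5)
            fac = 0.9 * enorm ** -0.14 * err_prev ** 0.08 if enorm > 0 else 5.0
            err_prev = max(enorm, 1e-10)
            h *= min(5.0, max(0.2, fac))
        else:
            h *= max(0.2, 0.9 * enorm ** -0.2)
        if h < h_min:
            raise IntegrationError(
                f"step-size underflow at t={t:.6g} (stiffness?)", t=t, state=y)
    return y, h


def integrate_network(net: CellNetwork, t_span: tuple[float, float], dt_cell: float,
                      rtol: float = 1e-7, atol: float = 1e-9,
                      callback=None) -> tuple[np.ndarray, np.ndarray]:
    """Advance the whole cell network over ``t_span`` and report on the dt_cell grid.

    Gap-junction currents are frozen at the start of each dt_cell step and
    refreshed on the grid (segregated coupling); within a step every cell is
    advanced by the adaptive Runge-Kutta-Merson scheme.

    Returns ``(t_grid, trajectory)`` with trajectory shaped
    (n_steps+1, n_cells, 3).  ``callback(t, states)`` runs after each grid
    step (used by the orchestrator to co-advance cross-bridge kinetics).
    """
    if dt_cell <= 0:
        raise ValueError("dt_cell must be positive")
    t0, t1 = t_span
    n_steps = max(1, int(round((t1 - t0) / dt_cell)))
    t_grid = t0 + dt_cell * np.arange(n_steps + 1)
    traj = np.empty((n_steps + 1, net.n_cells, 3))
    y = net.states.copy()
    traj[0] = y
    h = dt_cell
    for k in range(n_steps):
        frozen = coupling_all(net, y)

        def f(t, s, frozen=frozen):
            return network_rhs(net, s, coupling=frozen)

        y, h = _adaptive_span(f, t_grid[k], t_grid[k + 1], y, rtol, atol, h)
        if np.any(y[:, :2] < -1e-9):
            i = int(np.argmin(np.minimum(y[:, 0], y[:, 1])))
            raise NegativeConcentrationError(
                f"cell {i} reached negative concentration at t={t_grid[k + 1]:.4g}",
                t=t_grid[k + 1], state=y[i])
        traj[k + 1] = y
        if callback is not None:
            callback(t_grid[k + 1], y)
    net.states = y.copy()
    return t_grid, traj
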
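"""Block-segregated multiscale time loop and simulation configuration.

The solution procedure advances three subsystems with no feedback inside a
step:

1. **Cellular level** (fast, step dt_cell): Ca2+ dynamics by the adaptive
   Runge-Kutta-Merson scheme with gap-junction currents frozen on the
   dt_cell grid; cross-bridge kinetics by forward Euler at dt_cell.
2. **Contractile units** (step dt_solid): forward-Euler sliding update at
   every Gauss point using the stretch lam of the *previous* continuum step
   (lagged coupling) and cross-bridge states interpolated from the dt_cell
   grid onto dt_solid.
3. **Continuum** (step dt_solid): quasi-static Newton solve of the
   fibre-reinforced hyperelastic ring at fixed hook displacement; the hook
   reaction is the simulated myograph force.

A run consists of (i) a displacement-controlled loading phase that
calibrates the passive ring to the resting preload, (ii) a stationarity
pre-roll of the cellular variables, and (iii) the protocol phase.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cell_ionic import (CellNetwork, CellParams, DEFAULT_INITIAL_STATE,
                         integrate_network)
from .contractile_unit import CUParams, overlap, sliding_rate
from .crossbridge import CBParams, step_cb_arrays
from .continuum_fe import FESystem, TissueParams, hook_force, loading_phase
from .protocols import PopulationSpec, ProtocolSchedule, make_protocol, \
    randomize_population
from .ring_model import (RingGeometry, RingMesh, build_ring_mesh,
                         build_strip_mesh, circumferential_fibre, myograph_bcs,
                         write_vtk, write_timeseries_csv)

__all__ = [
    "SimulationConfig",
    "SimulationOutput",
    "run_simulation",
    "normalized_force",
    "interpolate_cb",
    "StageError",
]

class StageError(RuntimeError):
    """A simulation stage failed; carries the stage tag and partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: dict | None = None):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.manifest = manifest or {}


@dataclass
class SimulationConfig:
    """Full configuration of one multiscale run."""

    geometry: RingGeometry = field(default_factory=RingGeometry)
    resolution: tuple = (2, 24, 5)
    mesh_kind: str = "ring"                 # "ring" | "strip" | "none"
    cell: CellParams = field(default_factory=CellParams)
    cb: CBParams = field(default_factory=CBParams)
    cu: CUParams = field(default_factory=CUParams)
    tissue: TissueParams = field(default_factory=TissueParams)
    protocol: ProtocolSchedule | None = None
    phi_a_sd: float = 0.1                   # uM/s population scatter
    initial_state: tuple = DEFAULT_INITIAL_STATE   # (chi, zeta, eta) at t=-preroll
    cb_initial: tuple = (0.5, 0.0, 0.0)     # (n_Mp, n_AMp, n_AM): detached start
    dt_cell: float = 1e-3                   # s (Delta tau_1)
    dt_solid: float = 0.1                   # s (Delta tau_2)
    t_end: float = 10.0                     # s of protocol phase
    preroll: float = 200.0                  # s stationarity pre-roll
    t_intervention: float = 0.0             # s, F0 sample time
    preload_mN: float = 1.0
    seed: int = 0
    cell_rtol: float = 1e-7
    cell_atol: float = 1e-9
    newton_rtol: float = 1e-8
    record_cells: tuple = (0,)
    record_every: int = 1                   # force/cell cadence in solid steps
    vtk_every: int = 0                      # snapshots every k solid steps (0=off)
    out_dir: str | None = None
    mesh: RingMesh | None = None            # prebuilt mesh overrides mesh_kind

    def __post_init__(self):
        if self.dt_solid < self.dt_cell:
            raise ValueError("dt_solid must be >= dt_cell")
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")

    # -- serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "resolution": list(self.resolution),
            "mesh_kind": self.mesh_kind,
            "cell": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in asdict(self.cell).items()},
            "cb": asdict(self.cb), "cu": asdict(self.cu),
            "tissue": asdict(self.tissue),
            "protocol": None if self.protocol is None else {
                "name": self.protocol.name,
                "phi_a_mean": self.protocol.phi_a_mean,
                "overrides": self.protocol.overrides,
                "ramps": [asdict(r) for r in self.protocol.ramps],
            },
        }
        d["initial_state"] = list(self.initial_state)
        d["cb_initial"] = list(self.cb_initial)
        for k in ("phi_a_sd", "dt_cell", "dt_solid", "t_end", "preroll",
                  "t_intervention", "preload_mN", "seed", "cell_rtol",
                  "cell_atol", "newton_rtol", "record_every", "vtk_every",
                  "out_dir"):
            d[k] = getattr(self, k)
        d["record_cells"] = list(self.record_cells)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        from .protocols import Ramp
        kw = dict(d)
        if "geometry" in kw:
            kw["geometry"] = RingGeometry(**kw["geometry"])
        for key, typ in (("cell", CellParams), ("cb", CBParams),
                         ("cu", CUParams), ("tissue", TissueParams)):
            if key in kw:
                kw[key] = typ(**kw[key])
        if kw.get("protocol"):
            p = kw["protocol"]
            kw["protocol"] = ProtocolSchedule(
                name=p["name"], phi_a_mean=p.get("phi_a_mean", 0.6),
                overrides=p.get("overrides", {}),
                ramps=tuple(Ramp(**r) for r in p.get("ramps", ())))
        if "resolution" in kw:
            kw["resolution"] = tuple(kw["resolution"])
        if "record_cells" in kw:
            kw["record_cells"] = tuple(kw["record_cells"])
        if "initial_state" in kw:
            kw["initial_state"] = tuple(kw["initial_state"])
        if "cb_initial" in kw:
            kw["cb_initial"] = tuple(kw["cb_initial"])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SimulationOutput:
    """Results of one run."""

    t_force: np.ndarray
    force: np.ndarray                 # hook force (mN)
    normalized: np.ndarray            # F / F0
    F0: float
    preload_force: float
    hook_displacement: float
    cell_series: pd.DataFrame
    manifest: dict
    cell_traj: np.ndarray | None = None   # (n_rec+1, n_cells, 3) coarse record


def normalized_force(t: np.ndarray, force: np.ndarray,
                     t_intervention: float) -> tuple[np.ndarray, float]:
    """Force normalised by F0, the force at the first sample >= t_intervention."""
    t = np.asarray(t, dtype=float)
    force = np.asarray(force, dtype=float)
    idx = np.searchsorted(t, t_intervention)
    if idx >= len(t):
        raise ValueError("t_intervention beyond the simulated span")
    f0 = float(force[idx])
    if f0 <= 0:
        raise ValueError(f"F0 must be positive, got {f0}")
    return force / f0, f0


def interpolate_cb(t_grid: np.ndarray, cb_grid: np.ndarray, t: float) -> np.ndarray:
    """Linear-in-time interpolation of cross-bridge states between grids."""
    if t <= t_grid[0]:
        return cb_grid[0]
    if t >= t_grid[-1]:
        return cb_grid[-1]
    k = int(np.searchsorted(t_grid, t)) - 1
    w = (t - t_grid[k]) / (t_grid[k + 1] - t_grid[k])
    return (1 - w) * cb_grid[k] + w * cb_grid[k + 1]


def _build_mesh(cfg: SimulationConfig):
    if cfg.mesh is not None:
        mesh = cfg.mesh
    elif cfg.mesh_kind == "ring":
        mesh = build_ring_mesh(cfg.geometry, cfg.resolution)
    elif cfg.mesh_kind == "strip":
        mesh = build_strip_mesh(*cfg.resolution)
    else:
        raise ValueError(f"no mesh for mesh_kind={cfg.mesh_kind!r}")
    return mesh


def _fibre_for(mesh: RingMesh, kind: str) -> np.ndarray:
    if kind == "strip":
        f = np.zeros((mesh.n_elements, 8, 3))
        f[:, :, 0] = 1.0
        return f
    return circumferential_fibre(mesh)


def run_simulation(cfg: SimulationConfig) -> SimulationOutput:
    """Execute the full multiscale protocol (see module docstring)."""
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                "stages": []}
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: setup ---------------------------------------------------------
    try:
        mesh = _build_mesh(cfg)
        fibre = _fibre_for(mesh, cfg.mesh_kind)
        n_cells = mesh.n_elements
        protocol = cfg.protocol
        phi_mean = protocol.phi_a_mean if protocol is not None else cfg.cell.Phi_A
        pop = PopulationSpec(phi_a_mean=phi_mean, phi_a_sd=cfg.phi_a_sd,
                             seed=cfg.seed)
        phi_baseline = randomize_population(pop, n_cells) if cfg.phi_a_sd > 0 \
            else np.full(n_cells, phi_mean)
        fes = FESystem(mesh.nodes, mesh.elements, cfg.tissue, fibre)
        manifest["n_cells"] = n_cells
        manifest["stages"].append("setup")
    except Exception as exc:                                 # pragma: no cover
        raise StageError("setup", exc, manifest) from exc

    # --- stage: loading phase (passive preload) -------------------------------
    try:
        hook = mesh.node_sets["hook_contact"]
        base_bcs = myograph_bcs(mesh)
        if cfg.preload_mN > 0:
            sol, d_hook, f_pre = loading_phase(
                fes, hook, base_bcs, cfg.preload_mN,
                symmetry_factor=mesh.symmetry_factor)
        else:
            from .continuum_fe import _solve_at
            sol = _solve_at(fes, hook, base_bcs, 0.0, None)
            d_hook, f_pre = 0.0, 0.0
        manifest["hook_displacement_mm"] = d_hook
        manifest["preload_mN"] = f_pre
        manifest["stages"].append("loading")
    except Exception as exc:
        raise StageError("loading", exc, manifest) from exc

    if cfg.t_end == 0:
        t_f = np.array([0.0])
        force = np.array([f_pre])
        norm = np.array([1.0]) if f_pre > 0 else np.array([np.nan])
        return SimulationOutput(t_force=t_f, force=force, normalized=norm,
                                F0=f_pre, preload_force=f_pre,
                                hook_displacement=d_hook,
                                cell_series=pd.DataFrame(
                                    columns=["t", "cell_id", "chi", "zeta", "eta",
                                             "n_M", "n_Mp", "n_AMp", "n_AM"]),
                                manifest=manifest)

    # --- stages: multiscale pre-roll and protocol loop ------------------------
    # The coupled loop runs from t = -preroll (detached cross-bridges, initial
    # ionic state) through the protocol; ramps are evaluated at max(t, 0), so
    # the pre-roll sees the intervention's onset parameters and the Ca2+, CB
    # and CU variables reach stationary conditions with mechanics engaged
    # before the drug schedule starts.
    stage = "preroll"
    try:
        cell0, cb0 = (protocol.apply(cfg.cell, cfg.cb, 0.0, phi_baseline)
                      if protocol is not None else (cfg.cell, cfg.cb))
        net = CellNetwork(n_cells=n_cells,
                          params=_with_phi(cell0, phi_baseline, protocol),
                          adjacency=mesh.adjacency)
        net.states[:] = cfg.initial_state
        cb_state = [np.full(n_cells, cfg.cb_initial[0]),
                    np.full(n_cells, cfg.cb_initial[1]),
                    np.full(n_cells, cfg.cb_initial[2])]

        n_pre = int(round(cfg.preroll / cfg.dt_solid))
        n_solid = int(round(cfg.t_end / cfg.dt_solid))
        sub_per_solid = max(1, int(round(cfg.dt_solid / cfg.dt_cell)))
        u_fs = np.zeros((n_cells, 8))             # chemical sliding per gp
        active_prev = (np.zeros((n_cells, 8)), np.zeros((n_cells, 8)))
        lam_prev = fes.kinematics(sol.u)["lam"]   # lagged stretch
        t_force, force, records = [], [], []
        u_prev = sol.u
        for k in range(-n_pre, n_solid):
            t0, t1 = k * cfg.dt_solid, (k + 1) * cfg.dt_solid
            if k == 0:
                manifest["stages"].append("preroll")
                stage = "protocol"
            if protocol is not None:
                cell_t, cb_t = protocol.apply(cfg.cell, cfg.cb, max(t0, 0.0),
                                              phi_baseline)
                net.params = _with_phi(cell_t, phi_baseline, protocol)
            else:
                cb_t = cfg.cb

            def cb_step(t, states, cb_t=cb_t):
                cb_state[0], cb_state[1], cb_state[2] = step_cb_arrays(
                    cb_state[0], cb_state[1], cb_state[2],
                    np.maximum(states[:, 0], 0.0), cfg.dt_cell, cb_t)

            integrate_network(net, (t0, t1), (t1 - t0) / sub_per_solid,
                              rtol=cfg.cell_rtol, atol=cfg.cell_atol,
                              callback=cb_step)
            # contractile units: lagged-lam forward Euler at dt_solid
            n_amp = cb_state[1][:, None]
            n_am = cb_state[2][:, None]
            rate, _ = sliding_rate(lam_prev, u_fs, n_amp, n_am, cfg.cu)
            u_fs = u_fs + cfg.dt_solid * rate
            active = _active_arrays(u_fs, cb_state, cfg.cu)
            sol = _solve_with_active(fes, u_prev, active_prev, active,
                                     cfg.newton_rtol)
            active_prev = active
            u_prev = sol.u
            lam_prev = fes.kinematics(sol.u)["lam"]
            if t1 >= 0 and (k + 1) % cfg.record_every == 0:
                t_force.append(t1)
                force.append(hook_force(fes, sol, hook,
                                        symmetry_factor=mesh.symmetry_factor,
                                        active=active))
                _record_cells(records, t1, cfg, net, cb_state)
            if out_dir and cfg.vtk_every and t1 >= 0 \
                    and (k + 1) % cfg.vtk_every == 0:
                _snapshot(out_dir / f"state_{k + 1:06d}.vtk", mesh, fes, sol,
                          net, cb_state, u_fs, cfg)
        manifest["stages"].append("protocol")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc, manifest) from exc

    t_f = np.asarray(t_force)
    f_arr = np.asarray(force)
    try:
        norm, f0 = normalized_force(t_f, f_arr, cfg.t_intervention)
    except ValueError:       # unloaded fixtures develop force from zero
        norm, f0 = np.full_like(f_arr, np.nan), float("nan")
    cell_df = pd.DataFrame(records, columns=["t", "cell_id", "chi", "zeta", "eta",
                                             "n_M", "n_Mp", "n_AMp", "n_AM"])
    if out_dir:
        cell_df.to_csv(out_dir / "cells.csv", index=False)
        pd.DataFrame({"t": t_f, "force_mN": f_arr, "normalized": norm}).to_csv(
            out_dir / "force.csv", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return SimulationOutput(t_force=t_f, force=f_arr, normalized=norm, F0=f0,
                            preload_force=f_pre, hook_displacement=d_hook,
                            cell_series=cell_df, manifest=manifest)


def _solve_with_active(fes, u_prev, active_prev, active, rtol):
    """Newton solve; on failure, continue incrementally in active stress.

    Normally the active coefficients change only slightly between solid
    steps; the one large jump (attaching the contractile machinery after the
    pre-roll) is handled by blending from the previous step's coefficients.
    """
    from .continuum_fe import NewtonError
    try:
        return fes.newton_solve(u_prev, active=active, rtol=rtol)
    except NewtonError:
        pass
    for n_sub in (4, 16, 64):
        u = u_prev
        try:
            for s in range(1, n_sub + 1):
                w = s / n_sub
                blend = tuple((1 - w) * p + w * c
                              for p, c in zip(active_prev, active))
                sol = fes.newton_solve(u, active=blend, rtol=rtol)
                u = sol.u
            return sol
        except NewtonError:
            continue
    raise NewtonError("active-stress continuation failed")


def _with_phi(cell: CellParams, phi_baseline: np.ndarray,
              protocol: ProtocolSchedule | None) -> CellParams:
    """Ensure Phi_A carries the per-cell baseline when no ramp has set it."""
    from dataclasses import replace
    if protocol is not None and any(
            r.path == "cell.Phi_A" and r.mode == "scale" for r in protocol.ramps):
        return cell       # protocol.apply already scaled the per-cell baseline
    return replace(cell, Phi_A=phi_baseline)


def _active_arrays(u_fs, cb_state, cu: CUParams):
    n_att = (cb_state[1] + cb_state[2])[:, None]
    k_act = cu.mu_a * overlap(u_fs, cu) * n_att
    return np.broadcast_to(k_act, u_fs.shape), u_fs


def _record_cells(records, t, cfg, net, cb_state):
    for c in cfg.record_cells:
        if c >= net.n_cells:
            continue
        chi, zeta, eta = net.states[c]
        n_mp, n_amp, n_am = cb_state[0][c], cb_state[1][c], cb_state[2][c]
        records.append((t, c, chi, zeta, eta,
                        1 - n_mp - n_amp - n_am, n_mp, n_amp, n_am))


def _snapshot(path, mesh, fes, sol, net, cb_state, u_fs, cfg):
    kin = fes.kinematics(sol.u)
    fields = {
        "displacement": sol.u,
        "pressure": sol.pressure,
        "J_bar": kin["J_bar"],
        "chi": net.states[:, 0],
        "n_attached": cb_state[1] + cb_state[2],
        "u_fs": u_fs.mean(axis=1),
        "lam": kin["lam"].mean(axis=1),
    }
    write_vtk(mesh, fields, path)
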
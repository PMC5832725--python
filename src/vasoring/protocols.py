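"""Pharmacological intervention schedules and population randomisation.

Interventions are encoded as piecewise-linear parameter ramps applied to the
cell network after the Ca2+ and cross-bridge variables have reached
stationary conditions:

* ``phenylephrine`` -- alpha1-adrenergic vasoconstriction: the NSCC influx
  Phi_A of *each individual cell* is scaled by a factor of 7 over a drug
  dilution time dt_dil (50 or 100 s), taking the population mean from 0.6 to
  4.2 uM/s while preserving the coefficient of variation.
* ``cpa`` -- SERCA inhibition: the uptake rate B_SR ramps down.  Two printed
  variants ship: ``text`` (400 -> 350 uM/s over 2000 s, the default) and
  ``table`` (400 -> 200 uM/s over 1000 s).  Baseline Phi_A mean 0.8 uM/s.
  The enhancement coefficient theta for CPA must be supplied explicitly
  (candidate published values: 0.0, 3.0, 30.0 -- the source table is
  typographically ambiguous).
* ``ryanodine`` -- RyR blockade: the CICR rate C_Ry ramps from 1250 down to
  312.5 uM/s over 2000 s starting at t = 100 s, with store-operated entry
  switched on (A_S = 0.1) and theta = 0.5.  Baseline Phi_A mean 0.8 uM/s.

Cellular variability is modelled by randomising Phi_A with a normal
distribution (s.d. 0.1 uM/s); negative draws are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cell_ionic import CellParams
from .crossbridge import CBParams

__all__ = [
    "Ramp",
    "ProtocolSchedule",
    "PopulationSpec",
    "randomize_population",
    "ramp_value",
    "make_protocol",
    "PROTOCOL_NAMES",
]

PROTOCOL_NAMES = ("phenylephrine", "cpa", "ryanodine")

# Parameter paths a protocol may touch: "cell.<name>" or "cb.<name>".
_VALID_PREFIXES = ("cell.", "cb.")


@dataclass(frozen=True)
class Ramp:
    """Piecewise-linear variation of one parameter.

    ``mode='absolute'`` ramps the parameter value itself; ``mode='scale'``
    ramps a multiplicative factor applied to each cell's own baseline value
    (used for the per-cell phenylephrine scaling).
    """

    path: str
    t_start: float
    duration: float
    start: float
    end: float
    mode: str = "absolute"

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("ramp duration must be >= 0")
        if not self.path.startswith(_VALID_PREFIXES):
            raise ValueError(f"unknown parameter path {self.path!r}")
        if self.mode not in ("absolute", "scale"):
            raise ValueError("mode must be 'absolute' or 'scale'")


def ramp_value(ramp: Ramp, t: float) -> float:
    """Value of the ramped quantity at time t (start before, end after)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t <= ramp.t_start:
        return ramp.start
    if ramp.duration == 0 or t >= ramp.t_start + ramp.duration:
        return ramp.end
    frac = (t - ramp.t_start) / ramp.duration
    return ramp.start + frac * (ramp.end - ramp.start)


@dataclass
class ProtocolSchedule:
    """One pharmacological intervention: ramps plus static overrides."""

    name: str
    ramps: tuple = ()
    overrides: dict = field(default_factory=dict)   # path -> value, applied at t=0
    phi_a_mean: float = 0.6                          # baseline population mean (uM/s)

    def paths(self):
        return {r.path for r in self.ramps} | set(self.overrides)

    def apply(self, cell0: CellParams, cb0: CBParams, t: float,
              phi_a_baseline: np.ndarray | None = None
              ) -> tuple[CellParams, CBParams]:
        """Parameters at time t; only the declared paths are modified.

        ``phi_a_baseline`` supplies per-cell randomised Phi_A values for the
        multiplicative ramps.
        """
        cell_kw, cb_kw = {}, {}
        for path, v in self.overrides.items():
            self._put(path, v, cell_kw, cb_kw)
        for r in self.ramps:
            v = ramp_value(r, t)
            if r.mode == "scale":
                base = phi_a_baseline if phi_a_baseline is not None \
                    else getattr(cell0, r.path.split(".", 1)[1])
                self._put(r.path, np.asarray(base) * v, cell_kw, cb_kw)
            else:
                self._put(r.path, v, cell_kw, cb_kw)
        return replace(cell0, **cell_kw), replace(cb0, **cb_kw)

    @staticmethod
    def _put(path, v, cell_kw, cb_kw):
        scope, name = path.split(".", 1)
        target = cell_kw if scope == "cell" else cb_kw
        if scope == "cell" and not hasattr(CellParams(), name):
            raise ValueError(f"unknown cell parameter {name!r}")
        if scope == "cb" and not hasattr(CBParams(), name):
            raise ValueError(f"unknown cross-bridge parameter {name!r}")
        target[name] = v


@dataclass
class PopulationSpec:
    """Normal randomisation of the per-cell NSCC influx Phi_A."""

    phi_a_mean: float = 0.6   # uM/s
    phi_a_sd: float = 0.1     # uM/s
    seed: int = 0

    def __post_init__(self):
        if self.phi_a_sd < 0:
            raise ValueError("phi_a_sd must be >= 0")


def randomize_population(spec: PopulationSpec, n_cells: int) -> np.ndarray:
    """Seeded i.i.d. normal Phi_A draws; negative draws are redrawn."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(spec.seed)
    vals = rng.normal(spec.phi_a_mean, spec.phi_a_sd, size=n_cells)
    while np.any(vals < 0):
        bad = vals < 0
        vals[bad] = rng.normal(spec.phi_a_mean, spec.phi_a_sd, size=int(bad.sum()))
    return vals


def make_protocol(name: str, *, dt_dil: float = 50.0, t_start: float = 0.0,
                  cpa_variant: str = "text",
                  cpa_theta: float | None = None) -> ProtocolSchedule:
    """Build one of the named intervention schedules.

    ``t_start`` is the intervention onset (after the stationarity pre-roll);
    ``dt_dil`` applies to phenylephrine only.
    """
    if name == "phenylephrine":
        if dt_dil not in (50.0, 100.0):
            # the study used 50 and 100 s; other values are allowed but atypical
            pass
        return ProtocolSchedule(
            name=name, phi_a_mean=0.6,
            ramps=(Ramp("cell.Phi_A", t_start, dt_dil, 1.0, 7.0, mode="scale"),))
    if name == "cpa":
        if cpa_variant == "text":
            ramp = Ramp("cell.B_SR", t_start, 2000.0, 400.0, 350.0)
        elif cpa_variant == "table":
            ramp = Ramp("cell.B_SR", t_start, 1000.0, 400.0, 200.0)
        else:
            raise ValueError("cpa_variant must be 'text' or 'table'")
        if cpa_theta is None:
            raise ValueError(
                "theta for the CPA protocol must be supplied explicitly "
                "(published candidates: 0.0, 3.0, 30.0)")
        return ProtocolSchedule(name=name, phi_a_mean=0.8, ramps=(ramp,),
                                overrides={"cb.theta": float(cpa_theta)})
    if name == "ryanodine":
        return ProtocolSchedule(
            name=name, phi_a_mean=0.8,
            ramps=(Ramp("cell.C_Ry", t_start + 100.0, 2000.0, 1250.0, 312.5),),
            overrides={"cell.A_S": 0.1, "cb.theta": 0.5})
    raise ValueError(f"unknown protocol {name!r}; valid: {PROTOCOL_NAMES}")
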
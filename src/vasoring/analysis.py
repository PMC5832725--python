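"""Analysis helpers for oscillatory cell traces: peaks, phases, synchrony."""

from __future__ import annotations

import numpy as np

__all__ = ["peak_times", "oscillation_amplitude", "phase_order_parameter",
           "fluctuation_amplitude"]


def peak_times(t: np.ndarray, x: np.ndarray, rel_height: float = 0.5) -> np.ndarray:
    """Times of local maxima exceeding min + rel_height * range (parabolic refine)."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.empty(0)
    thr = x.min() + rel_height * (x.max() - x.min())
    core = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]) & (x[1:-1] > thr)
    idx = np.flatnonzero(core) + 1
    out = []
    for i in idx:
        denom = x[i - 1] - 2 * x[i] + x[i + 1]
        shift = 0.0 if denom == 0 else 0.5 * (x[i - 1] - x[i + 1]) / denom
        out.append(t[i] + shift * (t[min(i + 1, len(t) - 1)] - t[i]))
    return np.asarray(out)


def oscillation_amplitude(t, x, t_min: float = 0.0) -> float:
    """Peak-to-trough range of x over t >= t_min."""
    m = np.asarray(t) >= t_min
    xs = np.asarray(x)[m]
    return float(xs.max() - xs.min()) if xs.size else 0.0


def _phase_from_peaks(t_eval, pk):
    """Linear phase interpolation: 2*pi per inter-peak interval."""
    if len(pk) < 2:
        return None
    k = np.searchsorted(pk, t_eval) - 1
    k = np.clip(k, 0, len(pk) - 2)
    return 2 * np.pi * (k + (t_eval - pk[k]) / (pk[k + 1] - pk[k]))


def phase_order_parameter(t, chi_all, t_min: float = 0.0) -> float:
    """Phase order of the cells' Ca2+ oscillations: mean pairwise
    phase-locking value.

    Phases come from linear interpolation between chi peak times.  For every
    cell pair the phase-locking value |<exp(i(phi_c - phi_d))>_t| over the
    window [t_min, end] is computed and the result is averaged over pairs.
    Frequency-locked states score 1 regardless of fixed phase lags (coupled
    oscillator media synchronise into travelling waves, not zero-lag states),
    while independently drifting oscillators average towards 0.  Cells
    without two peaks in the window are treated as phase-constant.
    """
    t = np.asarray(t, dtype=float)
    chi_all = np.asarray(chi_all, dtype=float)   # (n_t, n_cells)
    window = t[t >= t_min]
    if window.size == 0:
        raise ValueError("empty evaluation window")
    phases = []
    for c in range(chi_all.shape[1]):
        pk = peak_times(t, chi_all[:, c])
        pk = pk[pk >= t_min - (pk[1] - pk[0] if len(pk) > 1 else 0)]
        ph = _phase_from_peaks(window, pk)
        phases.append(np.zeros_like(window) if ph is None else ph)
    phases = np.stack(phases, axis=1)
    z = np.exp(1j * phases)
    n = phases.shape[1]
    if n < 2:
        return 1.0
    # mean over pairs of |<z_c conj(z_d)>_t|, vectorised via the Gram matrix
    gram = np.abs(z.conj().T @ z) / z.shape[0]      # (n, n)
    iu = np.triu_indices(n, k=1)
    return float(gram[iu].mean())


def fluctuation_amplitude(t, series, t_min: float = 0.0,
                          detrend_window: float | None = None) -> float:
    """Fluctuation of a (force) series over the analysis window, relative to
    its mean.

    Without ``detrend_window`` this is the peak-to-peak range fraction.  With
    it, a moving average over the given span (seconds) is subtracted first
    and the RMS of the residual is returned -- the right statistic when slow
    equilibration drift would otherwise dominate the oscillatory band.
    """
    t = np.asarray(t, dtype=float)
    m = t >= t_min
    s = np.asarray(series, dtype=float)[m]
    if s.size == 0 or s.mean() == 0:
        return 0.0
    if detrend_window is None:
        return float((s.max() - s.min()) / abs(s.mean()))
    dt = np.median(np.diff(t[m]))
    w = max(2, int(round(detrend_window / dt)))
    if s.size <= 2 * w:
        raise ValueError("window too long for the available samples")
    resid = (s - np.convolve(s, np.ones(w) / w, mode="same"))[w:-w]
    return float(resid.std() / abs(s.mean()))
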
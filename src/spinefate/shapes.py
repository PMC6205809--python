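"""Analytic double-exponential transient shapes shared by generator and fitter."""

from __future__ import annotations

import numpy as np


def double_exp_peak_norm(tau_rise: float, tau_decay: float) -> float:
    """Peak value of exp(-t/tau_decay) - exp(-t/tau_rise) for t >= 0."""
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be < tau_decay")
    # peak time from d/dt = 0
    t_peak = (tau_rise * tau_decay / (tau_decay - tau_rise)) * np.log(tau_decay / tau_rise)
    return float(np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise))


def double_exp(t: np.ndarray, tau_rise: float, tau_decay: float,
               onset: float = 0.0) -> np.ndarray:
    """Unit-peak double exponential starting at ``onset``, zero before."""
    t = np.asarray(t, dtype=float)
    dt = t - onset
    out = np.zeros_like(dt)
    mask = dt >= 0
    out[mask] = np.exp(-dt[mask] / tau_decay) - np.exp(-dt[mask] / tau_rise)
    return out / double_exp_peak_norm(tau_rise, tau_decay)


def multi_onset_shape(t: np.ndarray, tau_rise: float, tau_decay: float,
                      onsets) -> np.ndarray:
    """Sum of unit-peak transients at several onsets, renormalised to unit peak.

    Overlapping transients can sum above one; the returned shape always
    peaks at exactly 1 so fitted amplitudes stay in ΔF/F_0 units.
    """
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    for onset in onsets:
        total += double_exp(t, tau_rise, tau_decay, onset)
    peak = total.max()
    if peak <= 0:
        raise ValueError("shape has no positive support on the given grid")
    return total / peak
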
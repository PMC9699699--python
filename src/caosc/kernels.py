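"""Event waveform kernel shared by the trace generator and the preset builder.

A spontaneous Ca2+ transient is modelled as an instantaneous-onset
double-exponential with an optional plateau::

    k(t) = (1 - exp(-t / rise_tau)) * exp(-max(0, t - plateau_s) / decay_tau)

for t >= 0 (zero before onset).  The rise term saturates with time constant
``rise_tau``; decay with constant ``decay_tau`` starts only after ``plateau_s``
seconds, which is how the pathological ultra-long transients of an
over-expressed indicator are emulated.  The kernel is dimensionless and is
scaled by a per-event amplitude in dF/F0 units.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = ["event_kernel", "kernel_fwhm"]


def event_kernel(
    t: np.ndarray | float,
    rise_tau: float,
    decay_tau: float,
    plateau_s: float = 0.0,
) -> np.ndarray:
    """Evaluate the unit-amplitude transient kernel at times ``t`` (seconds).

    Times before the event onset (t < 0) contribute zero.
    """
    if rise_tau <= 0 or decay_tau <= 0:
        raise ValueError("rise_tau and decay_tau must be positive")
    t = np.asarray(t, dtype=float)
    out = (1.0 - np.exp(-np.maximum(t, 0.0) / rise_tau)) * np.exp(
        -np.maximum(0.0, t - plateau_s) / decay_tau
    )
    return np.where(t < 0, 0.0, out)


def kernel_fwhm(rise_tau: float, decay_tau: float, plateau_s: float = 0.0) -> float:
    """Full width at half maximum of the noise-free kernel, in seconds.

    The peak is located on a dense grid and both half-maximum crossings are
    refined with Brent root finding; accuracy is limited only by float
    precision, so this serves as the ground-truth width for generated events.
    """
    t_max = plateau_s + 20.0 * decay_tau
    grid = np.linspace(0.0, t_max, 50_000)
    y = event_kernel(grid, rise_tau, decay_tau, plateau_s)
    i_pk = int(np.argmax(y))
    peak, t_pk = y[i_pk], grid[i_pk]
    half = peak / 2.0

    def f(x: float) -> float:
        return float(event_kernel(x, rise_tau, decay_tau, plateau_s)) - half

    eps = 1e-12
    t_up = brentq(f, eps, t_pk) if f(eps) < 0 else eps
    t_dn = brentq(f, t_pk, t_max)
    return t_dn - t_up
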
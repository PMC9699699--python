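"""Network synchrony and frequency-domain decomposition of oscillations.

Synchrony per field of view is the mean of all pairwise Spearman rank
correlation coefficients among the spontaneous dF/F0 traces of the view.
The spectral side computes a one-sided FFT amplitude spectrum,
2*sqrt(Re^2 + Im^2)/n per bin (DC and Nyquist not doubled), after mean
removal and without tapering, and integrates it over the three canonical
oscillation bands: ultra-slow (<10 mHz), slow (10-100 mHz) and fast
(100-300 mHz), reported as percentages of the three-band total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .extraction import DffTrace

__all__ = [
    "SynchronyResult",
    "SpectralDecomposition",
    "view_synchrony",
    "amplitude_spectrum",
    "band_fractions",
    "DEFAULT_BAND_EDGES_HZ",
]

#: Band edges in Hz: [0, 10 mHz), [10, 100 mHz), [100, 300 mHz].
DEFAULT_BAND_EDGES_HZ: tuple[float, float, float, float] = (0.0, 0.010, 0.100, 0.300)


@dataclass
class SynchronyResult:
    """Pairwise Spearman correlations of one view and their mean."""

    pair_matrix: np.ndarray     # (n_cells, n_cells), symmetric, diagonal 1
    mean_coefficient: float     # mean over the strict upper triangle
    n_cells: int


@dataclass
class SpectralDecomposition:
    """One-sided amplitude spectrum of a single trace."""

    freqs: np.ndarray           # Hz, ascending, up to Nyquist
    amplitude: np.ndarray       # per-bin FFT amplitude, >= 0
    n: int                      # input length
    fs: float


def view_synchrony(traces: list[DffTrace] | np.ndarray) -> SynchronyResult:
    """Mean pairwise Spearman correlation over all trace pairs of a view.

    Constant traces have undefined rank correlation; their pairs are
    recorded as NaN and excluded from the mean with a warning.
    """
    if isinstance(traces, np.ndarray):
        data = np.asarray(traces, dtype=float)
    else:
        lengths = {t.n for t in traces}
        if len(lengths) > 1:
            raise ValueError("all traces must have equal length")
        data = np.vstack([t.values for t in traces])
    n_cells = data.shape[0]
    if n_cells < 2:
        raise ValueError("need at least 2 traces")

    # variables in columns for spearmanr
    rho = stats.spearmanr(data.T).statistic
    if n_cells == 2:  # scipy returns a scalar for two variables
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)

    iu = np.triu_indices(n_cells, k=1)
    upper = rho[iu]
    if np.any(np.isnan(upper)):
        warnings.warn(
            "constant trace(s) produced undefined correlations; "
            "those pairs are excluded from the mean",
            RuntimeWarning,
            stacklevel=2,
        )
    mean = float(np.nanmean(upper))
    return SynchronyResult(pair_matrix=rho, mean_coefficient=mean, n_cells=n_cells)


def amplitude_spectrum(dff: DffTrace) -> SpectralDecomposition:
    """One-sided FFT amplitude spectrum of a mean-removed dF/F0 trace.

    Per-bin amplitude is 2*sqrt(Re^2+Im^2)/n for 0 < f < Nyquist; the DC
    and (for even n) Nyquist bins are not doubled.  Frequencies are
    k * fs / n.
    """
    x = dff.values
    n = x.size
    if n < 16:
        raise ValueError("need at least 16 samples for a spectrum")
    X = np.fft.rfft(x - x.mean())
    amp = 2.0 * np.abs(X) / n
    amp[0] = np.abs(X[0]) / n          # DC (≈0 after mean removal)
    if n % 2 == 0:
        amp[-1] = np.abs(X[-1]) / n    # Nyquist bin is unpaired
    freqs = np.fft.rfftfreq(n, d=1.0 / dff.fs)
    return SpectralDecomposition(freqs=freqs, amplitude=amp, n=n, fs=dff.fs)


def band_fractions(
    spec: SpectralDecomposition,
    edges_hz: tuple[float, float, float, float] = DEFAULT_BAND_EDGES_HZ,
) -> tuple[float, float, float]:
    """Percentage of spectral amplitude in the three oscillation bands.

    The amplitude is integrated (trapezoidal, on the native bin grid) over
    [e0, e1), [e1, e2) and [e2, e3]; each integral is reported as a percent
    of the three-band total.  Energy above the last edge is ignored by the
    percentages.  A band covered by fewer than two bins contributes zero
    with a warning; if the spectrum does not reach the last edge the fast
    band is flagged unavailable (NaN).
    """
    f, a = spec.freqs, spec.amplitude
    nyquist = spec.fs / 2.0
    fast_unavailable = nyquist < edges_hz[3]
    if fast_unavailable:
        warnings.warn(
            f"Nyquist {nyquist:.3f} Hz below the fast-band edge "
            f"{edges_hz[3]:.3f} Hz; fast band unavailable",
            RuntimeWarning,
            stacklevel=2,
        )

    integrals = []
    for i in range(3):
        lo, hi = edges_hz[i], edges_hz[i + 1]
        sel = (f >= lo) & ((f < hi) if i < 2 else (f <= hi))
        if sel.sum() < 2:
            warnings.warn(
                f"band [{lo}, {hi}] Hz covered by <2 frequency bins; "
                "its integral is zero",
                RuntimeWarning,
                stacklevel=2,
            )
            integrals.append(0.0)
        else:
            integrals.append(float(np.trapezoid(a[sel], f[sel])))
    if fast_unavailable:
        integrals[2] = np.nan
    total = np.nansum(integrals)
    if total == 0:
        return (0.0, 0.0, 0.0)
    pct = tuple(100.0 * v / total for v in integrals)
    return pct  # type: ignore[return-value]
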
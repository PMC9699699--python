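"""Raw fluorescence to dF/F0 conversion, neuropil correction and stimulus SNR.

Conventions follow standard ROI-mean imaging practice: fluorescence F is
background-subtracted, the baseline F0 is the mean of a small window of
samples at rest, dF/F0 = (F - F0) / F0, and neuropil contamination is
removed as F_cell(t) = F_measured(t) - r * F_neuropil(t) with r = 0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "RawTrace",
    "DffTrace",
    "compute_f0",
    "to_dff",
    "neuropil_correct",
    "stimulus_snr",
]


@dataclass
class RawTrace:
    """A sampled fluorescence trace in arbitrary units."""

    values: np.ndarray
    fs: float                       # sampling rate, Hz
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 10:
            raise ValueError("trace must be 1-D with at least 10 samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


@dataclass
class DffTrace:
    """A normalised dF/F0 trace (dimensionless)."""

    values: np.ndarray
    f0: float                       # baseline fluorescence used for normalisation
    fs: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


def compute_f0(
    trace: RawTrace | np.ndarray, n_rest: int = 5, mode: str = "search"
) -> float:
    """Baseline fluorescence F0 averaged from ``n_rest`` samples at rest.

    "At rest" is operationalised as the contiguous window of ``n_rest``
    samples with the minimal mean over the trace (``mode="search"``, the
    default), which deterministically avoids transients whenever a quiet
    stretch exists.  ``mode="first"`` instead averages the first ``n_rest``
    samples for recordings known to begin at rest.
    """
    x = trace.values if isinstance(trace, RawTrace) else np.asarray(trace, float)
    if x.size < n_rest:
        raise ValueError(f"trace has {x.size} samples, needs >= n_rest={n_rest}")
    if mode == "first":
        f0 = float(np.mean(x[:n_rest]))
    elif mode == "search":
        # sliding window means via cumulative sum
        c = np.concatenate(([0.0], np.cumsum(x)))
        window_means = (c[n_rest:] - c[:-n_rest]) / n_rest
        f0 = float(window_means.min())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if f0 <= 0:
        warnings.warn(
            f"non-positive baseline F0={f0:.4g}; dF/F0 normalisation will fail",
            RuntimeWarning,
            stacklevel=2,
        )
    return f0


def to_dff(trace: RawTrace, background: float, f0: float) -> DffTrace:
    """Convert a raw trace to dF/F0 given a scalar background and baseline.

    ``f0`` must have been computed on background-subtracted values;
    the result is ((F - background) - f0) / f0 sample-wise.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    values = ((trace.values - background) - f0) / f0
    return DffTrace(values=values, f0=f0, fs=trace.fs, meta=dict(trace.meta))


def neuropil_correct(
    measured: RawTrace, neuropil: RawTrace, r: float = 0.7
) -> RawTrace:
    """Subtract scaled neuropil signal: F_cell(t) = F_measured(t) - r * F_neuropil(t)."""
    if measured.n != neuropil.n:
        raise ValueError("measured and neuropil traces differ in length")
    if measured.fs != neuropil.fs:
        raise ValueError("measured and neuropil traces differ in sampling rate")
    return RawTrace(
        values=measured.values - r * neuropil.values,
        fs=measured.fs,
        meta=dict(measured.meta),
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (window of 1 is a no-op)."""
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    smoothed = np.convolve(x, kernel, mode="same")
    # fix the shrinking-window edges so edge samples average available points
    half = window // 2
    for i in range(half):
        smoothed[i] = x[: i + half + 1].mean()
        smoothed[-(i + 1)] = x[-(i + half + 1):].mean()
    return smoothed


def stimulus_snr(
    dff: DffTrace,
    onset_index: int,
    smooth_window: int = 3,
    response_window_s: float | None = None,
    stim_dur_s: float = 1.0,
) -> float:
    """Signal-to-noise ratio of a stimulus-aligned response.

    Numerator: maximum dF/F0 in the post-onset response window (by default
    stimulus duration + 1 s).  Denominator: standard deviation of the
    moving-average-filtered dF/F0 over the 1 s immediately before onset.
    A zero-variance baseline yields ``inf`` with a warning.
    """
    fs = dff.fs
    pre_samples = int(round(fs))
    if onset_index < pre_samples:
        raise ValueError("need at least 1 s of samples before stimulus onset")
    if response_window_s is None:
        response_window_s = stim_dur_s + 1.0
    stop = min(dff.n, onset_index + int(round(response_window_s * fs)) + 1)
    numerator = float(np.max(dff.values[onset_index:stop]))
    filtered = _moving_average(dff.values, smooth_window)
    baseline = filtered[onset_index - pre_samples : onset_index]
    noise_sd = float(np.std(baseline)) if baseline.size > 1 else 0.0
    if noise_sd == 0.0:
        warnings.warn(
            "zero-variance pre-onset baseline; SNR is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return numerator / noise_sd
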
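"""Detection and quantification of spontaneous/evoked Ca2+ events.

Detection follows the three-standard-deviations rule: an event is a local
maximum of the dF/F0 trace exceeding baseline-median + k*SD (k = 3 by
default).  The SD is by default estimated from the noise alone — the scaled
median absolute deviation of the first difference divided by sqrt(2) — so
that the threshold is not inflated by the events themselves; computing the
SD of the raw trace is available as an alternative mode.

Waveform metrics use the half-maximum convention: the FWHM is the time
between the upward and the downward crossing of the half-maximum level,
located by linear interpolation between bracketing samples; on/off rates
are the times to rise from 50% to maximum and to decay from maximum to 50%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extraction import DffTrace, RawTrace, compute_f0, to_dff
from .simulate import TrialSet

__all__ = [
    "EventTable",
    "detect_events",
    "event_frequency_mHz",
    "waveform_metrics",
    "trial_success_rate",
]

_MAD_TO_SD = 1.4826  # scaled MAD of a Gaussian equals its SD


@dataclass
class EventTable:
    """Detected events of one trace plus the detection context."""

    events: pd.DataFrame        # columns: peak_index, t_peak, amplitude,
                                #          t_on50, t_off50, fwhm
    duration_s: float
    cell_id: str | int | None
    threshold_used: float       # dF/F0 level above which peaks counted

    def __post_init__(self) -> None:
        t = self.events["t_peak"].to_numpy()
        if t.size and (np.any(np.diff(t) < 0) or t.min() < 0 or t.max() > self.duration_s):
            raise ValueError("events must be sorted and lie within the recording")

    def __len__(self) -> int:
        return len(self.events)


def _empty_event_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_index": pd.Series(dtype=int),
            "t_peak": pd.Series(dtype=float),
            "amplitude": pd.Series(dtype=float),
            "t_on50": pd.Series(dtype=float),
            "t_off50": pd.Series(dtype=float),
            "fwhm": pd.Series(dtype=float),
        }
    )


def noise_sd_estimate(x: np.ndarray) -> float:
    """Robust noise SD: scaled MAD of the first difference over sqrt(2)."""
    d = np.diff(x)
    return _MAD_TO_SD * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _excursion_regions(
    x: np.ndarray, thr_high: float, thr_low: float
) -> list[tuple[int, int]]:
    """Hysteresis excursions: start above thr_high, end below thr_low.

    Returns inclusive (start, end) index pairs.  A region opens at the
    first sample exceeding ``thr_high`` and runs while samples stay above
    ``thr_low``, so threshold jitter on a decaying flank does not split a
    transient into several counts.
    """
    regions: list[tuple[int, int]] = []
    i, n = 0, x.size
    while i < n:
        if x[i] > thr_high:
            j = i
            while j + 1 < n and x[j + 1] > thr_low:
                j += 1
            regions.append((i, j))
            i = j + 1
        else:
            i += 1
    return regions


def _region_peaks(x: np.ndarray, lo: int, hi: int, threshold: float) -> list[int]:
    """Local maxima above ``threshold`` inside [lo, hi] (plateaus: first sample)."""
    peaks: list[int] = []
    for i in range(lo, hi + 1):
        if x[i] <= threshold:
            continue
        left_ok = i == 0 or x[i - 1] < x[i]
        right_ok = i == x.size - 1 or x[i] >= x[i + 1]
        if left_ok and right_ok:
            peaks.append(i)
    return peaks


def _split_region(
    x: np.ndarray,
    lo: int,
    hi: int,
    threshold: float,
    baseline: float,
    split_frac: float,
    split_floor: float,
) -> list[tuple[int, int]]:
    """Split an excursion at qualifying valleys between adjacent peaks.

    For every pair of adjacent above-threshold local maxima the minimum
    between them is a split point when (a) both flanking peaks exceed the
    ``split_floor`` level while the valley falls below it — small wiggles
    on a decaying flank never justify a split — and (b) the valley
    amplitude (relative to baseline) falls below ``split_frac`` times the
    smaller flanking peak.  The criteria are relative, so noise riding on
    one tall transient never splits it.
    """
    peaks = _region_peaks(x, lo, hi, threshold)
    if len(peaks) < 2:
        return [(lo, hi)]
    cuts: list[int] = []
    for pa, pb in zip(peaks, peaks[1:]):
        m = pa + 1 + int(np.argmin(x[pa + 1 : pb + 1]))
        smaller = min(x[pa], x[pb]) - baseline
        if (
            min(x[pa], x[pb]) > split_floor
            and x[m] < split_floor
            and (x[m] - baseline) < split_frac * smaller
        ):
            cuts.append(m)
    if not cuts:
        return [(lo, hi)]
    starts = [lo] + [c + 1 for c in cuts]
    ends = cuts + [hi]
    return list(zip(starts, ends))


def detect_events(
    dff: DffTrace,
    k: float = 3.0,
    min_separation: float | None = None,
    sd_mode: str = "noise",
    release_k: float | None = None,
    min_width: int = 2,
    split_frac: float = 0.7,
    split_floor_k: float = 6.0,
    strong_k: float = 4.0,
) -> EventTable:
    """Detect events by the k-standard-deviations rule (default k = 3).

    An event is an excursion of the trace above the detection threshold
    (baseline median + k*SD) that ends only when the trace falls back
    below a release level (median + release_k*SD, default k - 1), i.e.
    hysteresis, so that noise jitter around the threshold on a slowly
    decaying flank does not split one transient into several counts.  An
    excursion must span at least ``min_width`` samples (default 2), which
    suppresses single-sample noise spikes; an excursion narrower than that
    is still kept when its peak exceeds ``strong_k`` standard deviations
    (default 4), since a single 4-sigma sample is vanishingly unlikely to be noise
    and transients lasting about one sample interval are otherwise lost.  An excursion containing
    several transients is split recursively at an interior valley that
    drops below ``split_frac`` (default 0.7) of the smaller flanking
    peak's amplitude, provided both flanking peaks exceed
    ``split_floor_k`` standard deviations (default 6) — relative criteria,
    so noise riding on a tall plateau or on a decaying flank never splits
    a single transient.  Each final excursion contributes one event
    at its maximum sample (ties: earliest); peaks closer than
    ``min_separation`` seconds (default ``2 / fs``) are merged into the
    taller one.  Waveform columns are left NaN; fill them with
    :func:`waveform_metrics`.
    """
    x = dff.values
    if x.size < 10:
        raise ValueError("trace must have at least 10 samples")
    fs = dff.fs
    if min_separation is None:
        min_separation = 2.0 / fs

    baseline = float(np.median(x))
    if sd_mode == "noise":
        sd = noise_sd_estimate(x)
    elif sd_mode == "raw":
        sd = float(np.std(x))
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    threshold = baseline + k * sd
    if sd == 0.0 and np.ptp(x) == 0.0:
        warnings.warn(
            "zero-variance trace: no events detectable", RuntimeWarning, stacklevel=2
        )

    if release_k is None:
        release_k = max(k - 1.0, 0.0)
    release = baseline + release_k * sd
    strong = baseline + strong_k * sd
    split_floor = baseline + split_floor_k * sd
    regions: list[tuple[int, int]] = []
    for lo, hi in _excursion_regions(x, threshold, release):
        regions.extend(
            _split_region(x, lo, hi, threshold, baseline, split_frac, split_floor)
        )
    regions = [
        (lo, hi)
        for lo, hi in regions
        if hi - lo + 1 >= min_width or np.max(x[lo : hi + 1]) > strong
    ]
    accepted = [int(lo + np.argmax(x[lo : hi + 1])) for lo, hi in regions]
    # enforce the minimal peak separation: keep the taller of two close peaks
    min_gap = min_separation * fs - 1e-9
    merged: list[int] = []
    for idx in accepted:
        if merged and idx - merged[-1] < min_gap:
            if x[idx] > x[merged[-1]]:
                merged[-1] = idx
        else:
            merged.append(idx)
    accepted = merged

    frame = _empty_event_frame()
    if accepted:
        frame = pd.DataFrame(
            {
                "peak_index": np.array(accepted, dtype=int),
                "t_peak": np.array(accepted) / fs,
                "amplitude": x[accepted] - baseline,
                "t_on50": np.nan,
                "t_off50": np.nan,
                "fwhm": np.nan,
            }
        )
    return EventTable(
        events=frame,
        duration_s=dff.duration_s,
        cell_id=dff.meta.get("cell_id"),
        threshold_used=threshold,
    )


def event_frequency_mHz(table: EventTable) -> float:
    """Event frequency in mHz: 1000 * count / duration."""
    if table.duration_s <= 0:
        raise ValueError("duration must be positive")
    return 1000.0 * len(table) / table.duration_s


def _interp_crossing(x: np.ndarray, i_lo: int, i_hi: int, level: float, fs: float) -> float:
    """Time where ``x`` crosses ``level`` between samples i_lo and i_hi."""
    x0, x1 = x[i_lo], x[i_hi]
    if x1 == x0:
        return i_lo / fs
    frac = (level - x0) / (x1 - x0)
    return (i_lo + frac * (i_hi - i_lo)) / fs


def waveform_metrics(dff: DffTrace, table: EventTable) -> EventTable:
    """Fill per-event FWHM and 50% on/off times in a detected event table.

    Each event owns a window bounded by the inter-event minima towards its
    neighbours (overlapping events are split there) or by the trace edges.
    The half-maximum level is halfway between the window minimum (local
    baseline) and the peak.  Events whose half-maximum crossings are
    truncated by the trace edge or by an overlapping neighbour get NaN
    metrics.
    """
    x = dff.values
    fs = dff.fs
    peaks = table.events["peak_index"].to_numpy(dtype=int)
    if peaks.size == 0:
        return table

    # window bounds: argmin between consecutive peaks; trace edges outside
    bounds_left = np.empty(peaks.size, dtype=int)
    bounds_right = np.empty(peaks.size, dtype=int)
    bounds_left[0] = 0
    bounds_right[-1] = x.size - 1
    for k in range(peaks.size - 1):
        between = slice(peaks[k], peaks[k + 1] + 1)
        split = peaks[k] + int(np.argmin(x[between]))
        bounds_right[k] = split
        bounds_left[k + 1] = split

    rows = {"t_on50": [], "t_off50": [], "fwhm": []}
    for p, lo, hi in zip(peaks, bounds_left, bounds_right):
        local_base = float(np.min(x[lo : hi + 1]))
        half = local_base + (x[p] - local_base) / 2.0

        t_up = np.nan
        for i in range(p, lo, -1):
            if x[i - 1] < half <= x[i]:
                t_up = _interp_crossing(x, i - 1, i, half, fs)
                break
        t_dn = np.nan
        for i in range(p, hi):
            if x[i] >= half > x[i + 1]:
                t_dn = _interp_crossing(x, i, i + 1, half, fs)
                break

        t_pk = p / fs
        rows["t_on50"].append(t_pk - t_up if np.isfinite(t_up) else np.nan)
        rows["t_off50"].append(t_dn - t_pk if np.isfinite(t_dn) else np.nan)
        rows["fwhm"].append(
            t_dn - t_up if np.isfinite(t_up) and np.isfinite(t_dn) else np.nan
        )

    events = table.events.copy()
    for col, vals in rows.items():
        events[col] = vals
    return EventTable(
        events=events,
        duration_s=table.duration_s,
        cell_id=table.cell_id,
        threshold_used=table.threshold_used,
    )


def trial_success_rate(
    trials: TrialSet,
    k: float = 3.0,
    response_window_s: float | None = None,
    n_rest: int = 5,
) -> float:
    """Fraction of trials whose post-onset response clears the baseline.

    A trial succeeds when its post-onset dF/F0 maximum (within stimulus
    duration + 1 s by default) exceeds the pre-onset baseline mean plus
    ``k`` pre-onset standard deviations.
    """
    if response_window_s is None:
        response_window_s = trials.stim_dur_s + 1.0
    fs = trials.fs
    onset = trials.onset_index
    stop_offset = int(round(response_window_s * fs)) + 1
    successes = 0
    for seg in trials.trials:
        raw = RawTrace(values=seg, fs=fs)
        f0 = compute_f0(
            RawTrace(values=seg - trials.preset.background_F, fs=fs), n_rest=n_rest
        )
        dff = to_dff(raw, trials.preset.background_F, f0).values
        pre = dff[:onset]
        level = float(np.mean(pre)) + k * float(np.std(pre))
        post_max = float(np.max(dff[onset : min(dff.size, onset + stop_offset)]))
        if post_max > level:
            successes += 1
    return successes / trials.n_trials
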
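"""Independent brute-force reference implementations used by the tests.

Everything here is written with plain Python loops and the statistics
module (no reuse of package internals) so that package results can be
checked against a second, independently coded route.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def brute_force_detect(
    x,
    fs: float,
    k: float = 3.0,
    min_separation: float | None = None,
    release_k: float | None = None,
    min_width: int = 2,
    split_frac: float = 0.7,
    split_floor_k: float = 6.0,
    strong_k: float = 4.0,
) -> list[int]:
    """Exhaustive-scan event detection; returns accepted peak indices.

    Re-derives the detection contract sample by sample: threshold at
    median + k*SD with the SD taken as scaled MAD of first differences
    over sqrt(2); hysteresis excursions releasing at (k-1)*SD; recursive
    valley splitting (both flanking peaks above split_floor_k*SD, valley
    below split_frac of the smaller); minimum width with a strong-peak
    exception; one peak per region at the earliest maximal sample; close
    peaks merged keeping the taller.
    """
    x = [float(v) for v in x]
    n = len(x)
    if min_separation is None:
        min_separation = 2.0 / fs
    med = statistics.median(x)
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    dmed = statistics.median(diffs)
    sd = 1.4826 * statistics.median([abs(d - dmed) for d in diffs]) / math.sqrt(2.0)
    thr = med + k * sd
    rel = med + (k - 1.0 if release_k is None else release_k) * sd
    strong = med + strong_k * sd
    floor = med + split_floor_k * sd

    # hysteresis scan
    regions = []
    i = 0
    while i < n:
        if x[i] > thr:
            j = i
            while j + 1 < n and x[j + 1] > rel:
                j += 1
            regions.append((i, j))
            i = j + 1
        else:
            i += 1

    def split(lo, hi):
        peaks = []
        for i in range(lo, hi + 1):
            if x[i] <= thr:
                continue
            left_ok = i == 0 or x[i - 1] < x[i]
            right_ok = i == n - 1 or x[i] >= x[i + 1]
            if left_ok and right_ok:
                peaks.append(i)
        if len(peaks) < 2:
            return [(lo, hi)]
        cuts = []
        for pa, pb in zip(peaks, peaks[1:]):
            m = min(range(pa + 1, pb + 1), key=lambda i: (x[i], i))
            smaller = min(x[pa], x[pb]) - med
            if (
                min(x[pa], x[pb]) > floor
                and x[m] < floor
                and (x[m] - med) < split_frac * smaller
            ):
                cuts.append(m)
        if not cuts:
            return [(lo, hi)]
        starts = [lo] + [c + 1 for c in cuts]
        ends = cuts + [hi]
        return list(zip(starts, ends))

    final = []
    for lo, hi in regions:
        final.extend(split(lo, hi))
    final = [
        (lo, hi)
        for lo, hi in final
        if hi - lo + 1 >= min_width or max(x[lo : hi + 1]) > strong
    ]
    peaks = []
    for lo, hi in final:
        best = lo
        for i in range(lo, hi + 1):
            if x[i] > x[best]:
                best = i
        peaks.append(best)

    min_gap = min_separation * fs - 1e-9
    merged: list[int] = []
    for idx in peaks:
        if merged and idx - merged[-1] < min_gap:
            if x[idx] > x[merged[-1]]:
                merged[-1] = idx
        else:
            merged.append(idx)
    return merged


def rank_then_pearson(a, b) -> float:
    """Spearman correlation as average ranks followed by textbook Pearson."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    ra, rb = ranks(list(a)), ranks(list(b))
    n = len(ra)
    ma, mb = sum(ra) / n, sum(rb) / n
    cov = sum((p - ma) * (q - mb) for p, q in zip(ra, rb))
    va = sum((p - ma) ** 2 for p in ra)
    vb = sum((q - mb) ** 2 for q in rb)
    return cov / math.sqrt(va * vb)


def groupby_profile(days, values):
    """Per-stage mean/SEM/n computed with explicit loops."""
    out = {}
    for d in sorted(set(days)):
        vals = [v for dd, v in zip(days, values) if dd == d and not np.isnan(v)]
        m = sum(vals) / len(vals)
        if len(vals) > 1:
            sd = math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))
            sem = sd / math.sqrt(len(vals))
        else:
            sem = float("nan")
        out[d] = (m, sem, len(vals))
    return out


def halfwidth_by_dense_grid(func, t_max: float, n_grid: int = 2_000_000) -> float:
    """FWHM of a positive pulse by dense-grid scanning (independent oracle)."""
    t = np.linspace(0.0, t_max, n_grid)
    y = func(t)
    i_pk = int(np.argmax(y))
    half = y[i_pk] / 2.0
    above = y >= half
    first = int(np.argmax(above))
    last = len(above) - 1 - int(np.argmax(above[::-1]))
    return t[last] - t[first]
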
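# Methods

## The measurement chain

Raw fluorescence F(t) per ROI is processed as in standard chronic-imaging
practice.  A scalar background (mean of a background ROI; for synthetic
data the generator's `background_F`) is subtracted first.  Where a
neuropil channel exists, contamination is removed sample-wise as
F_cell(t) = F_measured(t) − r·F_neuropil(t) with r = 0.7 by default.  The
baseline F₀ is the mean of the contiguous five-sample window with the
lowest mean over the trace — a deterministic operationalisation of
"samples at rest" that is robust whenever any quiet stretch exists; a
"first five samples" mode is available for recordings known to start at
rest.  The normalised signal is ΔF/F₀ = ((F − background) − F₀)/F₀.
ΔF/F₀ is scale-free: multiplying F and the background by any positive
constant leaves it unchanged (property-tested).

The stimulus SNR divides the maximum ΔF/F₀ in a post-onset response
window (stimulus duration + 1 s by default) by the standard deviation of
a centred moving-average-filtered ΔF/F₀ over the 1 s immediately before
onset (filter width 3 samples by default; width 1 disables it).  A
zero-variance baseline yields `inf` with a warning.

## Event detection: the 3-SD rule made operational

Detection follows the three-standard-deviations convention: events must
exceed baseline median + k·SD, k = 3.  The SD is estimated from the noise
rather than the raw trace — the scaled median absolute deviation of the
first difference divided by √2 — so that the events themselves do not
inflate the threshold (an `sd_mode="raw"` alternative exists).

A literal "every local maximum above threshold" rule fails in both
directions on realistic traces: on a pathological plateau transient tens
of seconds long every noise wiggle is a local maximum above threshold,
and on a slowly decaying flank threshold jitter splits one transient into
several.  The detector therefore counts *excursions*:

1. an excursion opens when the trace exceeds median + k·SD and closes
   only when it falls below a release level (median + (k−1)·SD) —
   hysteresis against jitter on decaying flanks;
2. an excursion narrower than 2 samples is discarded unless its peak
   exceeds 4 SD (a single 4-σ sample is vanishingly unlikely to be noise,
   and transients lasting about one sample interval would otherwise be
   lost at low sampling rates);
3. an excursion containing several transients is split at the valley
   between adjacent above-threshold local maxima when both flanking peaks
   rise above a 6-SD floor, the valley falls below that floor, and the
   valley amplitude is less than 0.7 of the smaller flanking peak.  All
   criteria are relative to the noise scale, so noise riding on one tall
   transient never splits it;
4. one event per final excursion, at its maximum sample (earliest on
   ties); peaks closer than `min_separation` (default 2/fs) are merged
   into the taller one.

All internals (k, release, widths, split fraction and floor) are keyword
arguments.  They were fixed once by validating detected event counts
against generator ground truth across the two extreme regimes — dense
narrow events (150 mHz, FWHM ≈ 0.3 s) and sparse plateaued events
(5–20 mHz, FWHM ≈ 2–23 s) — and the same values are used everywhere.
The detector equals an independently coded exhaustive-scan oracle on
seeded noise traces (tested on 200 of them).

Known, quantified biases at the study's 5 Hz sampling rate: at 150 mHz
about 6 % of event pairs arrive closer than ~0.4 s and are physically
unresolvable as separate peaks, so the detected frequency underestimates
the true rate by ~7 %; in sparse regimes residual noise excursions near
threshold add ~2–3 mHz.  Both are inside the sampling error of the
standard 30-cell × 600 s protocol.

Waveform metrics are computed per detected event in a window bounded by
the inter-event minima towards its neighbours (overlapping events are
split there).  The half-maximum level sits halfway between the window
minimum and the peak; crossing times are linearly interpolated between
bracketing samples.  FWHM is the time between the upward and downward
crossings; t_on50/t_off50 are the times from 50 % to maximum and from
maximum to 50 %.  Events whose crossings are cut off by the trace edge or
an overlapping neighbour get NaN metrics rather than biased ones.  FWHM
is invariant to adding a constant to the trace and to positive scaling
(property-tested).

## Synchrony and spectra

Per-view synchrony is the mean over the strict upper triangle of the
pairwise Spearman rank-correlation matrix of all ΔF/F₀ traces in the
view, with average ranks on ties.  Pairs involving a constant trace are
undefined; they are excluded from the mean with a warning.

The amplitude spectrum removes the mean, applies no taper, and reports
the one-sided FFT amplitude 2·√(Re² + Im²)/n per bin (DC and, for even n,
the Nyquist bin are not doubled), on the grid k·fs/n.  Mean removal only
(no detrending or windowing) keeps the amplitude formula literal and
matches a plain spreadsheet-style FFT.  Band fractions integrate the
amplitude trapezoidally over [0, 10), [10, 100) and [100, 300] mHz and
report each as a percent of the three-band total; energy above 300 mHz is
ignored by the percentages.  Band edges are configurable; a spectrum that
does not reach 300 mHz flags the fast band unavailable (NaN).

Per-view spectra are computed per cell and then averaged; computing them
on the view-mean trace instead is a caller decision (pass the mean trace).

## Morphometry

Masks are inputs; no segmentation is attempted.  N/C ratio is the
nuclear/cytosolic mean-intensity ratio, with nucleus-filled defined by a
strict ratio > 0.8 (a ratio exactly at the cutoff is excluded).  Soma
area is pixel count × pixel size².  Total neurite length skeletonizes the
binary mask to 1-px centerlines and sums adjacency steps (1 axial, √2
diagonal) × pixel size — so a "length-100" line means 100 steps, i.e. 101
pixels.  Sholl profiles count 8-connected runs of skeleton pixels inside
1-px annuli at multiples of the step radius, which counts crossings
rather than pixels and is insensitive to neurite thickness.  The image
contrast index is 1 − 2/(F/F_background + 1): zero when signal equals
background, asymptotically 1, strictly increasing, bounded in (−1, 1).

## The synthetic generator

Spontaneous activity per view is the superposition of a network-shared
Poisson train (rate = event_rate · shared_fraction, identical times *and
amplitudes* across cells — so a fully shared noise-free view is
bit-identical across cells and its synchrony is exactly 1) and per-cell
private Poisson trains.  Each event adds an amplitude-scaled kernel

    k(t) = (1 − e^(−t/rise_tau)) · e^(−max(0, t − plateau_s)/decay_tau)

in ΔF/F₀ space; the raw trace is background_F + baseline_F·(1 + Σk) plus
Gaussian noise of SD baseline_F · noise_sd.  Amplitudes are Gaussian,
clipped at 25 % of the mean so no event falls below the practical
detection floor.  One `SeedSequence` per view spawns one stream for the
shared train plus one per cell, so per-cell traces are reproducible when
`n_cells` changes.

Stage presets (editable via the pipeline config, printed by
`analysis/01_simulate.py`):

| DIV | rate mHz (healthy / toxic) | amp ΔF/F₀ | shared | rise/decay s | plateau s (toxic) | kernel FWHM s |
|----:|---------------------------:|----------:|-------:|-------------:|------------------:|--------------:|
|  3  | 150 / 150 | 0.30 / 0.30 | 0.05 | 0.06 / 0.28 | 0    | 0.33 / 0.33 |
|  6  | 150 / 150 | 0.35 / 0.35 | 0.10 | 0.08 / 0.35 | 0    | 0.42 / 0.42 |
| 10  | 104 / 104 | 0.45 / 0.45 | 0.30 | 0.15 / 0.70 | 0    | 0.82 / 0.82 |
| 14  |  72 /  40 | 0.60 / 0.45 | 0.50 | 0.25 / 1.00 | 2.0  | 1.23 / 2.52 |
| 17  |  55 /  20 | 0.80 / 0.40 | 0.65 | 0.30 / 1.40 | 5.0  | 1.65 / 5.76 |
| 21  |  38 /  10 | 1.00 / 0.35 | 0.75 | 0.35 / 1.70 | 12.0 | 1.98 / 12.9 |
| 28  |  20 /   5 | 1.20 / 0.30 | 0.85 | 0.40 / 2.00 | 22.0 | 2.31 / 23.1 |

The two frequency anchors (150 mHz in the first week, 20 mHz plateau at
DIV 28) are fixed; intermediate healthy rates interpolate log-linearly.
Amplitude values per stage are not anchored to any published number —
only their rising monotone trend is — and the same holds for
shared_fraction.  Kernel time constants rise with maturation; the
first-week kernel is deliberately brief (FWHM ≈ 0.3 s, in the range of
fast GCaMP6m transients) so that a 150 mHz train is resolvable at the
1–5 Hz sampling rates this kind of experiment uses.  Toxic presets equal
healthy ones through DIV 10 and diverge after; the DIV 28 toxic plateau
is solved numerically at build time so the toxic kernel FWHM is exactly
10× the healthy one.  Noise SD is 0.015 ΔF/F₀ for every preset,
baseline_F = 100 and background_F = 20 arbitrary units.

Trials place a stimulus-locked kernel of fixed amplitude at onset with
probability `response_prob`, after ≥1 s (default 2 s) of baseline; truth
flags record the injections.

Rendered neurons are a soma disk (area sampled per preset) with a
concentric nucleus disk at half the soma radius whose intensity is
nc_ratio × the cytosolic intensity, plus 3–7 straight neurite branches
radiating in distinct octants.  Branch directions are quantized to
multiples of 45°, so the chain-code length of the rasterized centerline
equals the Euclidean truth *exactly*; arbitrary angles would carry the
classical up-to-8 % chain-code overestimate and make "ground truth"
ambiguous.  Morphology presets anchor the DIV 28 somata at 300 µm²
(healthy) and 200 µm² (toxic), with neurite length following an
upward-plateau curve for healthy cultures and retracting after DIV 14
for toxic ones, and N/C ratio crossing the 0.8 cutoff only in the toxic
late stages.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: stagewise
rate/amplitude/width/synchrony trends, the toxic phenotype, neuropil
contamination (pipeline-level: a slow sinusoidal common signal added with
a known coefficient), and exact morphometric truth.  It does **not**
model refractoriness or quasi-periodicity (trains are Poisson, as the
truth-count statistics require), bleaching, movement, overlapping cells,
3-D morphology or curved/branching neurites.  Two visible consequences:
(1) spectra of Poisson trains of first-order kernels are flat at low
frequency with a ~1/f rolloff, so the 200-mHz-wide fast band integrates
comparably to the slow band and the slow-band *dominance* seen in real
mid-development recordings is not reproduced — tests assert the robust
trends instead (slow ≫ ultra-slow; fast share falls with maturation);
(2) measured Spearman synchrony grows with shared_fraction at fixed
activity (tested at 0/0.5/1) but dips again at the most mature stage,
where events are so sparse that most samples are noise-ranked.  Passing
tests therefore validate the measurement chain, not these aspects of
biological realism.

## Longitudinal statistics

Stage profiles are per-stage mean, SEM (SD/√n; NaN when n = 1) and n.
Growth rates are forward differences of stage means on the irregular DIV
grid, assigned to interval midpoints — derivatives of the mean curve, not
per-cell derivatives, since culture views do not track individual cells
across weeks.  Profile correlations are OLS fits on stage means
(unweighted by default); a zero-variance y profile returns R² = 0 with a
warning, a zero-variance x raises.  Group comparisons use the two-tailed
unpaired pooled-variance t-test for two groups, or one-way ANOVA followed
by all-pairs Bonferroni-adjusted t-tests (p·m capped at 1, m = g(g−1)/2),
with the conventional star coding (* p<0.05, ** p<0.01, *** p<0.001).

## Pipeline, sizes and determinism

The pipeline (`caosc.pipeline`, CLI `caosc`) runs simulate → analyze →
report from one YAML config with a versioned schema; unknown keys are
errors, every stage is a pure function of config + seed, outputs are
cached and reused, and identical config + seed gives byte-identical
metric tables.  The default experiment simulates 7 stages × 2 conditions,
30 cells × 600 s at 5 Hz per view and 8 images per stage/condition —
large enough that sampling error, not problem size, limits precision,
while the full analysis chain runs in seconds on one core.  The
acceptance protocols use the same 30 × 600 s views and 50-image cohorts.

One caveat worth stating: with 85 % shared events at DIV 28, the
network-shared train is a single Poisson realisation common to all 30
cells, so the sampling SE of the view-mean frequency is ≈5.3 mHz — about
a quarter of the 20 mHz plateau — and does not shrink with more cells.
Consistency checks at that stage therefore use the analytic SE
√(s·λT + (1−s)·λT/n)/T of the protocol, not the cross-cell SEM, which
would be misleadingly small.
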
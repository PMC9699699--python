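# caosc — chronic calcium-oscillation and morphology quantification

Genetically encoded calcium indicators (GECIs) of the GCaMP family make it
possible to watch neurons signal for weeks, but prolonged or strong
expression of conventional GCaMP perturbs the cells it reports on:
spontaneous Ca²⁺ oscillations slow down and widen, the indicator
accumulates in the nucleus, somata shrink and neurites retract.
Detoxified variants (GCaMP-X) avoid this, which makes *chronic*
quantification — following cultured cortical neurons from DIV 3 to DIV 28
(days in vitro) — both possible and necessary.

`caosc` is a tested, reusable implementation of that quantification chain
for people analysing slow spontaneous Ca²⁺ oscillations and neuronal
morphology:

- **signal extraction** — background subtraction, neuropil correction
  (F_cell = F_measured − r·F_neuropil, r = 0.7), baseline F₀ from five
  samples at rest, ΔF/F₀, stimulus-aligned SNR;
- **event metrics** — three-standard-deviations event detection on ΔF/F₀
  (robust MAD noise estimate, hysteresis excursions, sub-peak splitting),
  frequency in mHz, amplitude, FWHM and 50 % on/off times by linear
  interpolation, trial success rate;
- **synchrony & spectra** — mean pairwise Spearman rank correlation per
  field of view; one-sided FFT amplitude 2·√(Re²+Im²)/n with band
  fractions over <10 mHz (ultra-slow), 10–100 mHz (slow) and 100–300 mHz
  (fast);
- **morphometry** — nuclear/cytosolic intensity ratio with the 0.8
  nucleus-filling cutoff, soma area, skeleton-based total neurite length,
  Sholl profiles, the image-contrast index 1 − 2/(F/F_bg + 1);
- **longitudinal statistics** — per-stage mean ± SEM profiles, growth
  rates as first derivatives, profile-level OLS correlations, two-tailed
  Student's t-tests and one-way ANOVA with Bonferroni post hoc tests;
- **synthetic data** — a seeded generator that emulates the developmental
  regimes (event rate declining ≈150 → ≈20 mHz with rising amplitude and
  synchrony), the toxic-probe phenotype (collapsed rate/amplitude, ~10-fold
  FWHM, nuclear filling, ~200 vs ~300 µm² somata) and neuropil
  contamination, with exact ground truth for every quantity — so the whole
  chain is verifiable without microscope data.

## Worked example

```python
from caosc import (build_stage_presets, simulate_view, RawTrace, compute_f0,
                   to_dff, detect_events, waveform_metrics, event_frequency_mHz)

preset = build_stage_presets()[("DIV28", "healthy")]
view = simulate_view(preset, n_cells=30, duration_s=600, fs=5.0, seed=1)

raw = RawTrace(view.traces[0], fs=5.0)
f0 = compute_f0(RawTrace(raw.values - preset.background_F, fs=5.0))
dff = to_dff(raw, preset.background_F, f0)
table = waveform_metrics(dff, detect_events(dff))
print(len(table), event_frequency_mHz(table), table.events["fwhm"].mean())
```

prints `16 26.666666666666668 2.4412876949107556` for this cell:
16 detected events in 600 s (26.7 mHz — one realisation of the 20 mHz
plateau preset) with a mean FWHM of ≈2.4 s, close to the preset kernel's
true width of 2.31 s.

The numbered drivers under `analysis/` run the full experiment
(7 stages × 2 conditions, 30 cells × 600 s each, plus image cohorts) and
write tables under `results/run/`:

```bash
python analysis/01_simulate.py            # synthetic cohorts + ground truth
python analysis/02_extract_and_quantify.py
python analysis/03_profiles_and_stats.py
```

The second script reports, for example

```
healthy mean event frequency: DIV3 141.8 mHz -> DIV28 18.3 mHz
DIV28 mean FWHM: toxic 21.5 s vs healthy 2.2 s (9.6-fold)
DIV28 healthy: soma 302 um^2, neurites 885 um, nucleus-filled fraction 0.00
DIV28 toxic: soma 193 um^2, neurites 185 um, nucleus-filled fraction 1.00
```

i.e. the detection stage recovers the programmed developmental decline of
the oscillation frequency, the ~10-fold FWHM widening of the toxic probe,
and the late-stage morphological divergence; the third script adds the
longitudinal statistics (inverse frequency-vs-neurite-length correlation,
positive amplitude-vs-length correlation, bell-shaped growth-rate curves
peaking around DIV 10, and significant DIV 28 healthy-vs-toxic contrasts).

A `caosc` command-line entry point wraps the same pipeline
(`caosc all --seed 7 --out results/run`) and can emit single synthetic
artifacts (`caosc simulate-one view --preset DIV28:healthy --seed 1 --out d/`).

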
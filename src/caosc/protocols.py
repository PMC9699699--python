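"""Standard measurement protocols composed from the library primitives.

These are the end-to-end recipes used to validate the pipeline against the
generator: simulate a view, run extraction and 3-SD detection with default
parameters, and summarise frequency or waveform width per cell; or render
an image cohort and summarise soma area.  Keeping them here guarantees the
analysis scripts, the test suite and the acceptance script all measure the
same way.
"""

from __future__ import annotations

import numpy as np

from .events import detect_events, event_frequency_mHz, waveform_metrics
from .extraction import RawTrace, compute_f0, to_dff
from .imaging import render_neuron_image
from .morphometry import soma_area
from .presets import MorphPreset, StagePreset
from .simulate import simulate_view

__all__ = [
    "view_event_analysis",
    "frequency_protocol",
    "fwhm_protocol",
    "soma_cohort_protocol",
    "frequency_standard_error_mHz",
    "spawn_seeds",
]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2**31) derived from one base seed."""
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def view_event_analysis(
    preset: StagePreset,
    n_cells: int = 30,
    duration_s: float = 600.0,
    fs: float = 5.0,
    seed: int = 1,
):
    """Simulate one view and run extraction + detection + waveform metrics.

    Returns ``(per-cell frequencies in mHz, pooled per-event FWHM array)``.
    """
    view = simulate_view(preset, n_cells, duration_s, fs, seed)
    freqs: list[float] = []
    fwhms: list[float] = []
    for c in range(n_cells):
        raw = RawTrace(view.traces[c], fs, meta={"cell_id": c})
        f0 = compute_f0(RawTrace(raw.values - preset.background_F, fs))
        dff = to_dff(raw, preset.background_F, f0)
        table = waveform_metrics(dff, detect_events(dff))
        freqs.append(event_frequency_mHz(table))
        fwhms.extend(table.events["fwhm"].dropna().tolist())
    return np.asarray(freqs), np.asarray(fwhms)


def frequency_protocol(
    preset: StagePreset,
    n_cells: int = 30,
    duration_s: float = 600.0,
    fs: float = 5.0,
    seed: int = 1,
) -> float:
    """Mean detected event frequency (mHz) across the cells of one view."""
    freqs, _ = view_event_analysis(preset, n_cells, duration_s, fs, seed)
    return float(freqs.mean())


def fwhm_protocol(
    preset: StagePreset,
    n_cells: int = 30,
    duration_s: float = 600.0,
    fs: float = 5.0,
    seed: int = 1,
) -> float:
    """Mean measured event FWHM (s) pooled over all events of one view."""
    _, fwhms = view_event_analysis(preset, n_cells, duration_s, fs, seed)
    return float(fwhms.mean())


def soma_cohort_protocol(
    morph: MorphPreset, n_images: int = 50, seed: int = 3
) -> float:
    """Mean measured soma area (um^2) over a cohort of rendered neurons."""
    areas = [
        soma_area(
            render_neuron_image(morph, s).masks["soma"], morph.pixel_size
        )
        for s in spawn_seeds(seed, n_images)
    ]
    return float(np.mean(areas))


def frequency_standard_error_mHz(
    preset: StagePreset, n_cells: int, duration_s: float
) -> float:
    """Sampling SE (mHz) of the cell-mean event frequency of one view.

    The network-shared Poisson train is a single realisation common to all
    cells, so its variance does not average out across cells:
    Var(mean count) = s*lambda*T + (1 - s)*lambda*T / n.
    """
    lam, s = preset.event_rate, preset.shared_fraction
    var_mean_count = s * lam * duration_s + (1.0 - s) * lam * duration_s / n_cells
    return 1000.0 * float(np.sqrt(var_mean_count)) / duration_s
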
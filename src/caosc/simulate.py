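"""Synthetic trace generator with ground truth.

Spontaneous activity is a superposition of two Poisson processes: a
network-shared train (rate ``event_rate * shared_fraction``) whose event
times are identical across all cells of a view, and a per-cell private
train (rate ``event_rate * (1 - shared_fraction)``).  Each event adds an
amplitude-scaled transient kernel (see :mod:`caosc.kernels`) in dF/F0
space; the raw trace is then

    F(t) = background_F + baseline_F * (1 + sum of kernels) + noise,

with i.i.d. Gaussian noise of standard deviation ``baseline_F * noise_sd``.
Ground-truth event times and amplitudes are returned alongside the traces.

Randomness uses one :class:`numpy.random.SeedSequence` per view, spawned
into one child stream for the shared train plus one per cell, so per-cell
traces are reproducible even when ``n_cells`` changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import event_kernel
from .presets import StagePreset

__all__ = ["SyntheticView", "TrialSet", "simulate_view", "simulate_trials"]

#: Amplitudes are Gaussian but clipped to this fraction of the mean so that
#: no event is generated below the practical detection floor.
_MIN_AMP_FRACTION = 0.25


@dataclass
class SyntheticView:
    """One simulated field of view with ground truth."""

    traces: np.ndarray                      # (n_cells, n_samples) raw fluorescence
    fs: float
    truth_events: list[tuple[np.ndarray, np.ndarray]]  # per cell (times s, amps dF/F0)
    truth_shared_times: np.ndarray          # network event times, s
    preset: StagePreset
    seed: int

    def __post_init__(self) -> None:
        if self.traces.shape[0] != len(self.truth_events):
            raise ValueError("trace count and truth list count must match")
        duration = self.traces.shape[1] / self.fs
        for times, amps in self.truth_events:
            if times.size != amps.size:
                raise ValueError("event time and amplitude arrays must match")
            if times.size and (times.min() < 0 or times.max() > duration):
                raise ValueError("truth event time outside the recording")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.fs


@dataclass
class TrialSet:
    """Stimulus-aligned trial segments with ground-truth response flags."""

    trials: list[np.ndarray]                # raw fluorescence segments
    onset_index: int                        # stimulus onset, samples
    truth_response_flags: np.ndarray        # bool per trial
    fs: float
    stim_dur_s: float
    preset: StagePreset
    seed: int

    def __post_init__(self) -> None:
        if len(self.trials) != self.truth_response_flags.size:
            raise ValueError("flags length must equal trial count")
        for seg in self.trials:
            if not 0 <= self.onset_index < seg.size:
                raise ValueError("onset index outside trial segment")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _poisson_times(rng: np.random.Generator, rate: float, duration_s: float) -> np.ndarray:
    """Sorted event times of a homogeneous Poisson process on [0, duration)."""
    count = rng.poisson(rate * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=count))


def _sum_kernels(
    t_grid: np.ndarray,
    times: np.ndarray,
    amps: np.ndarray,
    preset: StagePreset,
) -> np.ndarray:
    signal = np.zeros_like(t_grid)
    for t_e, a in zip(times, amps):
        start = int(np.searchsorted(t_grid, t_e))
        if start >= t_grid.size:
            continue
        signal[start:] += a * event_kernel(
            t_grid[start:] - t_e, preset.rise_tau, preset.decay_tau, preset.plateau_s
        )
    return signal


def _sample_amplitudes(
    rng: np.random.Generator, n: int, preset: StagePreset
) -> np.ndarray:
    amps = rng.normal(preset.amplitude_mean, preset.amplitude_sd, size=n)
    return np.maximum(amps, _MIN_AMP_FRACTION * preset.amplitude_mean)


def simulate_view(
    preset: StagePreset,
    n_cells: int,
    duration_s: float,
    fs: float,
    seed: int,
) -> SyntheticView:
    """Simulate one field of view of ``n_cells`` cells for ``duration_s`` seconds."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration_s must be positive")
    n_samples = int(round(duration_s * fs))
    if n_samples < 10:
        raise ValueError("duration_s * fs must give at least 10 samples")

    streams = np.random.SeedSequence(seed).spawn(n_cells + 1)
    rng_shared = np.random.default_rng(streams[0])
    shared_times = _poisson_times(
        rng_shared, preset.event_rate * preset.shared_fraction, duration_s
    )
    # network events carry one amplitude realisation common to all cells,
    # so a fully shared noise-free view has bit-identical traces
    shared_amps = _sample_amplitudes(rng_shared, shared_times.size, preset)

    t_grid = np.arange(n_samples) / fs
    traces = np.empty((n_cells, n_samples))
    truth: list[tuple[np.ndarray, np.ndarray]] = []
    private_rate = preset.event_rate * (1.0 - preset.shared_fraction)
    for c in range(n_cells):
        rng = np.random.default_rng(streams[c + 1])
        private_times = _poisson_times(rng, private_rate, duration_s)
        private_amps = _sample_amplitudes(rng, private_times.size, preset)
        all_times = np.concatenate([shared_times, private_times])
        all_amps = np.concatenate([shared_amps, private_amps])
        order = np.argsort(all_times, kind="stable")
        times, amps = all_times[order], all_amps[order]
        dff = _sum_kernels(t_grid, times, amps, preset)
        noise = (
            rng.normal(0.0, preset.noise_sd * preset.baseline_F, size=n_samples)
            if preset.noise_sd > 0
            else 0.0
        )
        traces[c] = preset.background_F + preset.baseline_F * (1.0 + dff) + noise
        truth.append((times, amps))

    return SyntheticView(
        traces=traces,
        fs=fs,
        truth_events=truth,
        truth_shared_times=shared_times,
        preset=preset,
        seed=seed,
    )


def simulate_trials(
    preset: StagePreset,
    n_trials: int,
    response_prob: float,
    response_amp: float,
    fs: float,
    seed: int,
    pre_s: float = 2.0,
    post_s: float = 8.0,
    stim_dur_s: float = 1.0,
) -> TrialSet:
    """Simulate stimulus-aligned trials with probabilistic evoked responses.

    Each trial has ``pre_s`` seconds of baseline before the stimulus onset;
    with probability ``response_prob`` a stimulus-locked kernel of amplitude
    ``response_amp`` is injected at onset.  Truth flags record injections.
    """
    if not 0.0 <= response_prob <= 1.0:
        raise ValueError("response_prob must lie in [0, 1]")
    if pre_s < 1.0 or int(round(pre_s * fs)) < max(2, int(round(fs))):
        raise ValueError("trials need at least 1 s of pre-onset baseline")
    n_samples = int(round((pre_s + post_s) * fs))
    onset_index = int(round(pre_s * fs))
    t_grid = np.arange(n_samples) / fs

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    flags = rng.random(n_trials) < response_prob
    trials: list[np.ndarray] = []
    for k in range(n_trials):
        dff = np.zeros(n_samples)
        if flags[k]:
            dff[onset_index:] = response_amp * event_kernel(
                t_grid[onset_index:] - t_grid[onset_index],
                preset.rise_tau,
                preset.decay_tau,
                preset.plateau_s,
            )
        noise = (
            rng.normal(0.0, preset.noise_sd * preset.baseline_F, size=n_samples)
            if preset.noise_sd > 0
            else 0.0
        )
        trials.append(preset.background_F + preset.baseline_F * (1.0 + dff) + noise)

    return TrialSet(
        trials=trials,
        onset_index=onset_index,
        truth_response_flags=flags,
        fs=fs,
        stim_dur_s=stim_dur_s,
        preset=preset,
        seed=seed,
    )
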
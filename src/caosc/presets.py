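"""Stage presets for the synthetic chronic-imaging experiment.

Cultured cortical neurons develop over roughly four weeks in vitro (DIV,
days in vitro).  Spontaneous Ca2+ activity starts out fast, small and
unsynchronised, and matures into slow, large, network-wide oscillations:
the event rate falls from about 150 mHz in the first week to a plateau
around 20 mHz by DIV 28, while amplitude and synchrony rise.  A cytotoxic
indicator ("toxic" condition) tracks the healthy trajectory through DIV 10
and then collapses: rate and amplitude drop, and transients acquire a long
plateau that widens the FWHM roughly ten-fold by DIV 28.  Morphologically
the toxic condition shows nuclear filling of the indicator (N/C ratio above
the 0.8 cutoff), shrunken somata (~200 um^2 vs ~300 um^2 healthy) and
retracting neurites.

The two printed frequency anchors (150 mHz at DIV 3, 20 mHz at DIV 28) are
connected by log-linear interpolation over the intermediate stages.
Amplitude values per stage are not published; the presets use relative,
monotonically increasing amplitudes chosen to keep every event comfortably
above the detection floor.  All values live in the tables below and can be
overridden via the pipeline config.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from scipy.optimize import brentq

from .kernels import kernel_fwhm

__all__ = [
    "StagePreset",
    "MorphPreset",
    "STAGE_DAYS",
    "build_stage_presets",
    "build_morph_presets",
]

#: Developmental stages covered by the synthetic experiment.
STAGE_DAYS: tuple[int, ...] = (3, 6, 10, 14, 17, 21, 28)

Condition = Literal["healthy", "toxic"]

#: Fold change in FWHM of the toxic late-stage transient relative to healthy.
TOXIC_FWHM_FOLD = 10.0


@dataclass(frozen=True)
class StagePreset:
    """Generative parameters for one developmental stage and condition."""

    stage_label: str          # e.g. "DIV28"
    condition: str            # "healthy" | "toxic"
    event_rate: float         # spontaneous events per second
    shared_fraction: float    # probability an event comes from the network train
    amplitude_mean: float     # dF/F0
    amplitude_sd: float       # dF/F0
    rise_tau: float           # s
    decay_tau: float          # s
    plateau_s: float          # s; 0 for healthy, large for toxic late stages
    noise_sd: float           # dF/F0 units (scaled by baseline_F in raw traces)
    baseline_F: float         # arbitrary fluorescence units
    background_F: float       # arbitrary fluorescence units

    def __post_init__(self) -> None:
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude_mean <= 0:
            raise ValueError("amplitude_mean must be positive")

    @property
    def event_rate_mHz(self) -> float:
        return self.event_rate * 1000.0

    @property
    def day(self) -> int:
        return int(self.stage_label.removeprefix("DIV"))


@dataclass(frozen=True)
class MorphPreset:
    """Generative parameters for rendered neuron images at one stage."""

    stage_label: str
    condition: str
    soma_area_mean: float     # um^2
    soma_area_sd: float       # um^2
    total_length_mean: float  # um of neurite per neuron
    total_length_sd: float    # um
    nc_ratio_mean: float      # nuclear / cytosolic mean intensity
    nc_ratio_sd: float
    pixel_size: float = 0.5   # um per pixel
    branch_count_range: tuple[int, int] = (3, 7)

    def __post_init__(self) -> None:
        if min(self.soma_area_mean, self.total_length_mean) <= 0:
            raise ValueError("area and length means must be positive")
        if self.nc_ratio_mean < 0:
            raise ValueError("nc_ratio_mean must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


# ---------------------------------------------------------------------------
# Healthy trajectory.  Rates: anchors 150 mHz (first week) and 20 mHz
# (DIV 28); intermediate stages are log-linear between DIV 6 and DIV 28.
# Amplitude / shared_fraction rise monotonically; kernels slow with age.
# ---------------------------------------------------------------------------
#   day  rate(ev/s) shared  amp   rise  decay
_HEALTHY = {
    3:  (0.150, 0.05, 0.30, 0.06, 0.28),
    6:  (0.150, 0.10, 0.35, 0.08, 0.35),
    10: (0.104, 0.30, 0.45, 0.15, 0.70),
    14: (0.072, 0.50, 0.60, 0.25, 1.00),
    17: (0.055, 0.65, 0.80, 0.30, 1.40),
    21: (0.038, 0.75, 1.00, 0.35, 1.70),
    28: (0.020, 0.85, 1.20, 0.40, 2.00),
}

# Toxic divergence after DIV 10: collapsed rate/amplitude, growing plateau.
# The DIV-28 plateau is solved numerically below so the kernel FWHM is
# exactly TOXIC_FWHM_FOLD times the healthy DIV-28 kernel FWHM.
#   day  rate(ev/s) shared  amp   rise  decay plateau
_TOXIC_TAIL = {
    14: (0.040, 0.30, 0.45, 0.25, 1.00, 2.0),
    17: (0.020, 0.28, 0.40, 0.30, 1.40, 5.0),
    21: (0.010, 0.25, 0.35, 0.35, 1.70, 12.0),
    28: (0.005, 0.20, 0.30, 0.40, 2.00, None),
}

_NOISE_SD = 0.015
_BASELINE_F = 100.0
_BACKGROUND_F = 20.0


def _solve_toxic_plateau(rise: float, decay: float, healthy_fwhm: float) -> float:
    """Plateau length giving a kernel FWHM of TOXIC_FWHM_FOLD x healthy."""
    target = TOXIC_FWHM_FOLD * healthy_fwhm
    return brentq(
        lambda p: kernel_fwhm(rise, decay, p) - target, 0.1, 40.0 * healthy_fwhm
    )


def build_stage_presets() -> dict[tuple[str, str], StagePreset]:
    """Return presets keyed by ``(stage_label, condition)`` for all stages.

    Toxic presets equal the healthy ones through DIV 10 and diverge after.
    """
    presets: dict[tuple[str, str], StagePreset] = {}
    for day, (rate, shared, amp, rise, decay) in _HEALTHY.items():
        label = f"DIV{day}"
        presets[(label, "healthy")] = StagePreset(
            stage_label=label,
            condition="healthy",
            event_rate=rate,
            shared_fraction=shared,
            amplitude_mean=amp,
            amplitude_sd=0.2 * amp,
            rise_tau=rise,
            decay_tau=decay,
            plateau_s=0.0,
            noise_sd=_NOISE_SD,
            baseline_F=_BASELINE_F,
            background_F=_BACKGROUND_F,
        )

    h28 = presets[("DIV28", "healthy")]
    fwhm_h28 = kernel_fwhm(h28.rise_tau, h28.decay_tau)
    for day in STAGE_DAYS:
        label = f"DIV{day}"
        if day <= 10:
            presets[(label, "toxic")] = replace(
                presets[(label, "healthy")], condition="toxic"
            )
            continue
        rate, shared, amp, rise, decay, plateau = _TOXIC_TAIL[day]
        if plateau is None:
            plateau = _solve_toxic_plateau(rise, decay, fwhm_h28)
        presets[(label, "toxic")] = StagePreset(
            stage_label=label,
            condition="toxic",
            event_rate=rate,
            shared_fraction=shared,
            amplitude_mean=amp,
            amplitude_sd=0.2 * amp,
            rise_tau=rise,
            decay_tau=decay,
            plateau_s=plateau,
            noise_sd=_NOISE_SD,
            baseline_F=_BASELINE_F,
            background_F=_BACKGROUND_F,
        )
    return presets


# ---------------------------------------------------------------------------
# Morphology trajectories.  Soma anchors at DIV 28: ~300 um^2 healthy,
# ~200 um^2 toxic; neurite length follows an upward-plateau curve for the
# healthy condition and retracts after DIV 14 for the toxic one.  N/C ratio
# crosses the 0.8 nuclear-filling cutoff only in the toxic late stages.
# ---------------------------------------------------------------------------
#   day  soma   length  nc
_MORPH_HEALTHY = {
    3:  (120.0, 150.0, 0.40),
    6:  (150.0, 300.0, 0.40),
    10: (190.0, 500.0, 0.40),
    14: (230.0, 700.0, 0.40),
    17: (260.0, 820.0, 0.42),
    21: (285.0, 880.0, 0.42),
    28: (300.0, 900.0, 0.45),
}
_MORPH_TOXIC_TAIL = {
    14: (230.0, 650.0, 0.55),
    17: (228.0, 500.0, 0.75),
    21: (215.0, 350.0, 0.95),
    28: (200.0, 200.0, 1.10),
}


def build_morph_presets() -> dict[tuple[str, str], MorphPreset]:
    """Morphology presets keyed by ``(stage_label, condition)``."""
    presets: dict[tuple[str, str], MorphPreset] = {}
    for day in STAGE_DAYS:
        label = f"DIV{day}"
        for condition in ("healthy", "toxic"):
            table = _MORPH_HEALTHY
            if condition == "toxic" and day > 10:
                table = _MORPH_TOXIC_TAIL
            soma, length, nc = table[day]
            presets[(label, condition)] = MorphPreset(
                stage_label=label,
                condition=condition,
                soma_area_mean=soma,
                soma_area_sd=0.10 * soma,
                total_length_mean=length,
                total_length_sd=0.12 * length,
                nc_ratio_mean=nc,
                nc_ratio_sd=0.08,
            )
    return presets
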
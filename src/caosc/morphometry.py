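"""Morphometric indices from 2-D neuron images and their masks.

Masks are inputs (from the synthetic renderer or the user); no segmentation
is attempted here.  Indices: the nuclear/cytosolic mean-intensity ratio
with the 0.8 nuclear-filling cutoff, soma area, skeleton-based total
neurite length, the Sholl intersection profile, and the image-contrast
index 1 - 2/(F/F_background + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label
from skimage.morphology import skeletonize

__all__ = [
    "MorphRecord",
    "NC_CUTOFF",
    "nc_ratio_and_class",
    "soma_area",
    "total_neurite_length",
    "sholl_profile",
    "image_contrast",
]

#: N/C ratio above which a cell is classified as nucleus-filled.
NC_CUTOFF = 0.8


@dataclass
class MorphRecord:
    """Morphometric summary of one neuron image."""

    nc_ratio: float
    nuclear_class: str                      # "nucleus_excluded" | "nucleus_filled"
    soma_area: float                        # um^2
    total_neurite_length: float             # um
    sholl: list[tuple[float, int]] | None = None   # (radius um, crossings)
    contrast: float | None = None           # in (-1, 1)


def nc_ratio_and_class(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cytosol_mask: np.ndarray,
    cutoff: float = NC_CUTOFF,
) -> tuple[float, str]:
    """Nuclear/cytosolic mean-intensity ratio and nuclear-filling class.

    The class is ``nucleus_filled`` iff the ratio strictly exceeds the
    cutoff (default 0.8); a ratio exactly at the cutoff is excluded.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cytosol_mask = np.asarray(cytosol_mask, dtype=bool)
    if not nucleus_mask.any() or not cytosol_mask.any():
        raise ValueError("masks must be non-empty")
    if np.any(nucleus_mask & cytosol_mask):
        raise ValueError("nucleus and cytosol masks must be disjoint")
    cyt_mean = float(np.mean(image[cytosol_mask]))
    if cyt_mean == 0:
        raise ValueError("zero cytosolic mean intensity")
    ratio = float(np.mean(image[nucleus_mask])) / cyt_mean
    cls = "nucleus_filled" if ratio > cutoff else "nucleus_excluded"
    return ratio, cls


def soma_area(soma_mask: np.ndarray, pixel_size: float) -> float:
    """Soma area in um^2: pixel count times pixel_size squared."""
    soma_mask = np.asarray(soma_mask, dtype=bool)
    if not soma_mask.any():
        raise ValueError("empty soma mask")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return float(soma_mask.sum()) * pixel_size**2


def _chain_length_px(skeleton: np.ndarray) -> float:
    """Sum of steps between 8-adjacent skeleton pixels: 1 axial, sqrt(2) diagonal."""
    s = np.asarray(skeleton, dtype=bool)
    axial = np.count_nonzero(s[:, :-1] & s[:, 1:]) + np.count_nonzero(
        s[:-1, :] & s[1:, :]
    )
    diag = np.count_nonzero(s[:-1, :-1] & s[1:, 1:]) + np.count_nonzero(
        s[:-1, 1:] & s[1:, :-1]
    )
    return axial + np.sqrt(2.0) * diag


def total_neurite_length(neurite_mask: np.ndarray, pixel_size: float) -> float:
    """Total neurite length in um from a binary mask.

    The mask is skeletonized to 1-px centerlines and the length is the sum
    of steps between adjacent skeleton pixels (1 for axial, sqrt(2) for
    diagonal) scaled by the pixel size.  An empty mask yields 0 with a
    warning.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    mask = np.asarray(neurite_mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty neurite mask; length is 0", RuntimeWarning, stacklevel=2)
        return 0.0
    skel = skeletonize(mask)
    return _chain_length_px(skel) * pixel_size


def sholl_profile(
    skeleton: np.ndarray,
    soma_center: tuple[float, float],
    step: float,
    max_radius: float,
    pixel_size: float = 1.0,
) -> list[tuple[float, int]]:
    """Sholl analysis: neurite crossings of concentric circles around the soma.

    For each radius (``step``, ``2*step``, ... up to ``max_radius``, in um)
    the skeleton pixels falling inside the 1-px-wide annulus at that radius
    are grouped into 8-connected runs; each run counts as one crossing.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    skel = np.asarray(skeleton, dtype=bool)
    r0, c0 = soma_center
    if not (0 <= r0 < skel.shape[0] and 0 <= c0 < skel.shape[1]):
        raise ValueError("soma center lies outside the image")
    rr, cc = np.indices(skel.shape)
    dist = np.hypot(rr - r0, cc - c0)

    profile: list[tuple[float, int]] = []
    radius = step
    while radius <= max_radius + 1e-9:
        r_px = radius / pixel_size
        annulus = np.abs(dist - r_px) <= 0.5
        crossing_pixels = skel & annulus
        n_runs = int(label(crossing_pixels, connectivity=2).max())
        profile.append((radius, n_runs))
        radius += step
    return profile


def image_contrast(F: float, F_background: float) -> float:
    """Image-contrast index: 1 - 2 / (F / F_background + 1).

    Zero when the signal equals the background, approaching 1 as the
    signal dominates; strictly increasing in F/F_background and bounded
    in (-1, 1).
    """
    if F_background <= 0:
        raise ValueError("F_background must be positive")
    return 1.0 - 2.0 / (F / F_background + 1.0)
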
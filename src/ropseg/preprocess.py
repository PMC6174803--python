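"""Liver-window preprocessing: histogram windowing, contrast stretch, median smoothing.

The liver gray peak on abdominal CT sits in a narrow band (commonly
130–150 gray units).  Preprocessing keeps only pixels inside that window,
stretches the surviving band linearly to [1, out_max] (the low edge maps to
1, not 0, so preserved pixels never collide with the zeroed background),
and smooths with a 5×5 median filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BBox2D, crop

DEFAULT_WINDOW = (130.0, 150.0)


class EstimationError(ValueError):
    """The statistics patch cannot support a window estimate."""


@dataclass(frozen=True)
class LiverWindow:
    low: float = DEFAULT_WINDOW[0]
    high: float = DEFAULT_WINDOW[1]

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"window low {self.low} must be < high {self.high}")

    @property
    def midpoint(self):
        return 0.5 * (self.low + self.high)


def estimate_liver_window(image, patch_bbox: BBox2D = None,
                          min_half_width: float = 5.0) -> LiverWindow:
    """Estimate the liver window from the gray histogram of an image patch.

    The window is ``[peak − w, peak + w]`` where the peak is the histogram
    mode of the patch and ``w`` its half-width at half-maximum, floored at
    `min_half_width` gray units.  With no patch the default (130, 150)
    window is returned.
    """
    if patch_bbox is None:
        return LiverWindow(*DEFAULT_WINDOW)
    patch = crop(np.asarray(image, dtype=float), patch_bbox)
    lo, hi = patch.min(), patch.max()
    if hi - lo < 1e-12:
        raise EstimationError("constant patch: gray histogram has no peak")
    # unit-width bins over the observed range
    edges = np.arange(np.floor(lo), np.ceil(hi) + 2.0)
    counts, edges = np.histogram(patch, bins=edges)
    k = int(np.argmax(counts))
    peak = 0.5 * (edges[k] + edges[k + 1])
    half_max = counts[k] / 2.0
    left = k
    while left > 0 and counts[left - 1] >= half_max:
        left -= 1
    right = k
    while right < counts.size - 1 and counts[right + 1] >= half_max:
        right += 1
    w = max(min_half_width, 0.5 * (edges[right + 1] - edges[left]))
    return LiverWindow(peak - w, peak + w)


def window_and_stretch(image, window: LiverWindow = None,
                       out_max: float = 255.0) -> np.ndarray:
    """Zero out-of-window pixels; map [low, high] linearly onto [1, out_max]."""
    window = window or LiverWindow()
    img = np.asarray(image, dtype=np.float64)
    inside = (img >= window.low) & (img <= window.high)
    scaled = 1.0 + (img - window.low) * (out_max - 1.0) / (window.high - window.low)
    return np.where(inside, scaled, 0.0)


def median5(image) -> np.ndarray:
    """5×5 median filter with edge-replicated borders."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 5:
        raise ValueError(f"median5 requires a 2D image at least 5×5, got {img.shape}")
    return ndimage.median_filter(img, size=5, mode="nearest")


def preprocess_slice(image, patch_bbox: BBox2D = None, window: LiverWindow = None,
                     out_max: float = 255.0) -> np.ndarray:
    """Window → stretch → 5×5 median, in that order.

    An explicit `window` wins over `patch_bbox` estimation; with neither,
    the default (130, 150) window applies.
    """
    if window is None:
        window = estimate_liver_window(image, patch_bbox)
    return median5(window_and_stretch(image, window, out_max=out_max))
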
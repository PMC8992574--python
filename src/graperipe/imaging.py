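"""Berry segmentation, skin-color extraction, RGB->HSI conversion, compactness.

Segmentation follows the classic pipeline for fruit photographed on a
near-white reference board: convert to grayscale (unweighted channel mean,
which equals the HSI intensity), split with Otsu's between-class-variance
threshold, take the darker class as foreground, and keep the largest
8-connected component with holes filled as the region of interest.

The HSI conversion uses the max-channel piecewise hue rules:

    I = (R + G + B) / 3
    S = 1 - 3 min(R, G, B) / (R + G + B)
    H = 60 (G - B) / (max - min)          if R is the maximum
    H = 60 (B - R) / (max - min) + 120    if G is the maximum
    H = 60 (R - G) / (max - min) + 240    if B is the maximum

with hue wrapped into [0, 360).  Achromatic pixels (max == min) take H = 0,
and pure black takes S = 0 (both formulas are 0/0 there; the limit
conventions keep the conversion total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RGBTriple",
    "HSITriple",
    "SegmentationResult",
    "DegenerateHistogramError",
    "EmptyForegroundError",
    "otsu_threshold",
    "segment_berries",
    "extract_mean_rgb",
    "rgb_to_hsi",
    "compactness",
]

RGBTriple = tuple[float, float, float]
HSITriple = tuple[float, float, float]


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two populated gray levels."""


class EmptyForegroundError(ValueError):
    """Thresholding left no foreground pixels."""


@dataclass
class SegmentationResult:
    mask: np.ndarray        # bool, all foreground pixels
    threshold: int          # pixels with gray < threshold are the dark class
    n_components: int       # 8-connected foreground components
    roi_mask: np.ndarray    # bool, largest component with holes filled


def otsu_threshold(gray_histogram) -> int:
    """Threshold maximizing between-class variance for a gray-level histogram.

    Returns ``t`` such that the two classes are ``level < t`` and
    ``level >= t``; both classes are nonempty.  Ties are broken by the lowest
    qualifying ``t``.

    Raises :class:`DegenerateHistogramError` for a single-valued histogram.
    """
    counts = np.asarray(gray_histogram, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be a 1-D array of bin counts")
    if np.any(counts < 0):
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("histogram has fewer than 2 populated levels")

    levels = np.arange(counts.size, dtype=float)
    total = counts.sum()
    total_mass = (counts * levels).sum()
    w0 = np.cumsum(counts)[:-1]          # class 0 = levels < t, t = 1..n-1
    m0 = np.cumsum(counts * levels)[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    var = np.full(w0.shape, -np.inf)
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=w0 > 0)
    mu1 = np.divide(total_mass - m0, w1, out=np.zeros_like(m0), where=w1 > 0)
    var[valid] = (w0 * w1)[valid] * (mu0 - mu1)[valid] ** 2
    return int(np.argmax(var)) + 1       # argmax takes the first (lowest) tie


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def segment_berries(image: np.ndarray, dark_foreground: bool = True) -> SegmentationResult:
    """Separate berries from the reference-board background.

    ``dark_foreground=True`` (the default) assumes fruit darker than the
    board; pass ``False`` for bright fruit on a dark background.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    gray = np.rint(image.astype(float).mean(axis=2)).astype(int)
    hist = np.bincount(gray.ravel(), minlength=256)
    t = otsu_threshold(hist)
    mask = gray < t if dark_foreground else gray >= t
    if not mask.any():
        raise EmptyForegroundError("no foreground pixels after thresholding")
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    roi = ndimage.binary_fill_holes(labels == largest)
    return SegmentationResult(mask=mask, threshold=t, n_components=int(n), roi_mask=roi)


def extract_mean_rgb(image: np.ndarray, mask: np.ndarray) -> RGBTriple:
    """Arithmetic per-channel mean over mask-true pixels, unrounded."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes disagree")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    sel = image[mask]
    return tuple(float(v) for v in sel.mean(axis=0))


def rgb_to_hsi(rgb) -> HSITriple:
    """Convert one RGB triple (channels in [0, 255]) to (H deg, S, I)."""
    r, g, b = (float(v) for v in rgb)
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise ValueError("RGB channels must lie in [0, 255]")
    total = r + g + b
    i = total / 3.0
    mn = min(r, g, b)
    mx = max(r, g, b)
    s = 0.0 if total == 0 else 1.0 - 3.0 * mn / total
    if mx == mn:
        h = 0.0
    elif r == mx:
        h = 60.0 * (g - b) / (mx - mn)
    elif g == mx:
        h = 60.0 * (b - r) / (mx - mn) + 120.0
    else:
        h = 60.0 * (r - g) / (mx - mn) + 240.0
    h %= 360.0
    return (h, s, i)


def compactness(long_diam: float, horiz_diam: float, actual_area: float) -> float:
    """Bounding-box area (longitudinal x horizontal diameter) over fruit area."""
    if long_diam <= 0 or horiz_diam <= 0:
        raise ValueError("diameters must be positive")
    if actual_area <= 0:
        raise ValueError("actual fruit area must be positive")
    return (long_diam * horiz_diam) / actual_area
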
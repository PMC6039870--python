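"""Pixel-wise ratiometric BRET maps from dual-channel bioluminescence images.

A dual-view adapter splits emission into a short (460 band-pass) and a long
(535 band-pass) wavelength image of the same field.  The two views are never
perfectly registered, so the long channel is first aligned by an integer-
pixel rigid translation; each channel is then median-filtered, background-
subtracted and thresholded on the short-channel (donor) intensity, and the
BRET map is the per-pixel long/short ratio on the surviving foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "ImagePair",
    "RegistrationResult",
    "BretMap",
    "register_translation",
    "apply_shift",
    "compute_bret_map",
]


@dataclass
class ImagePair:
    """Short- and long-wavelength views of one field (same shape, counts)."""

    ch_short: np.ndarray
    ch_long: np.ndarray

    def __post_init__(self) -> None:
        self.ch_short = np.asarray(self.ch_short, dtype=float)
        self.ch_long = np.asarray(self.ch_long, dtype=float)
        if self.ch_short.shape != self.ch_long.shape:
            raise ValueError("channel images must have identical shapes")
        if self.ch_short.ndim != 2:
            raise ValueError("channel images must be 2-D")
        if np.any(self.ch_short < 0) or np.any(self.ch_long < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass(frozen=True)
class RegistrationResult:
    shift: tuple[int, int]  # (dy, dx): displacement of ch_long vs ch_short
    ncc: float
    low_confidence: bool  # best shift sits on the search-window boundary


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        raise ValueError("constant image: correlation undefined")
    return float(np.sum(a * b) / denom)


def register_translation(pair: ImagePair, max_shift: int = 5) -> RegistrationResult:
    """Integer shift of the long channel relative to the short channel.

    Exhaustive search over the (2*max_shift+1)^2 window for the shift
    maximizing the normalized cross-correlation of the overlapping region.
    Ties break toward the smaller |shift| (squared norm), then row-major
    order.  If the optimum sits on the window boundary the true shift may
    lie outside it; the result is flagged low-confidence.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    h, w = pair.ch_short.shape
    if np.ptp(pair.ch_short) == 0 or np.ptp(pair.ch_long) == 0:
        raise ValueError("constant image: correlation undefined")

    best = None
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            # ch_long displaced by (dy, dx): compare short[y] with long[y+dy]
            ys0, ys1 = max(0, -dy), min(h, h - dy)
            xs0, xs1 = max(0, -dx), min(w, w - dx)
            if ys1 <= ys0 or xs1 <= xs0:
                continue
            a = pair.ch_short[ys0:ys1, xs0:xs1]
            b = pair.ch_long[ys0 + dy: ys1 + dy, xs0 + dx: xs1 + dx]
            try:
                score = _ncc(a, b)
            except ValueError:
                continue
            key = (-score, dy * dy + dx * dx, dy, dx)
            if best is None or key < best[0]:
                best = (key, (dy, dx), score)
    if best is None:
        raise ValueError("no valid overlap in search window")
    (_, shift, score) = best
    on_edge = max_shift > 0 and (
        abs(shift[0]) == max_shift or abs(shift[1]) == max_shift
    )
    return RegistrationResult(shift=shift, ncc=score, low_confidence=on_edge)


def apply_shift(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate an image by integer pixels (wrap-around roll)."""
    return np.roll(image, (-shift[0], -shift[1]), axis=(0, 1))


@dataclass
class BretMap:
    """Per-pixel long/short ratio on the thresholded foreground."""

    ratio: np.ndarray  # NaN outside the mask
    mask: np.ndarray
    kernel: int
    background_percentile: float
    threshold: float


def compute_bret_map(
    pair: ImagePair,
    kernel: int = 3,
    background_percentile: float = 5.0,
    threshold: float = 1.0,
) -> BretMap:
    """Median-filter, background-subtract, threshold, divide.

    Per channel: a k x k median filter (edge-replicated), then subtraction
    of that channel's ``background_percentile``-th intensity percentile
    (clamped at 0).  The foreground mask keeps pixels whose processed
    short-channel value exceeds ``threshold`` (> 0 by default, so division
    by zero is impossible by construction); the ratio is long/short there
    and NaN elsewhere.  An empty mask is a valid result, not an error.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    if not (0.0 <= background_percentile < 100.0):
        raise ValueError("background percentile must be in [0, 100)")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")

    def process(img: np.ndarray) -> np.ndarray:
        sm = median_filter(img, size=kernel, mode="nearest")
        # b = 0 disables subtraction (the 0th percentile would subtract the
        # channel minimum, destroying uniform fields)
        bg = np.percentile(sm, background_percentile) if background_percentile > 0 else 0.0
        return np.maximum(sm - bg, 0.0)

    short = process(pair.ch_short)
    long_ = process(pair.ch_long)
    mask = short > threshold
    ratio = np.full(short.shape, np.nan)
    np.divide(long_, short, out=ratio, where=mask)
    return BretMap(
        ratio=ratio,
        mask=mask,
        kernel=kernel,
        background_percentile=background_percentile,
        threshold=threshold,
    )
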
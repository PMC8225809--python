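"""Noise reduction and global-threshold segmentation of single channels.

The pipeline's segmentation is deliberately simple: an iterated 3x3 median
filter (200 passes by default) removes speckle while preserving the spheroid
boundary, and Otsu's method picks one global threshold per channel by
minimising the within-class intensity variance of the histogram.  Foreground
is strictly greater than the threshold.  Disconnected foreground components
are all retained — fragmented spheroids are legitimate biology, so no
largest-component selection is performed anywhere.

Morphometrics derived from the mask: pixel area, area normalised to the
24 h reference, and the *extent* (area over minimal bounding-box area),
a roundness/compactness proxy in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateInputError, NoForegroundError, NormalisationError
from .io import ChannelImage

__all__ = [
    "FilterParams",
    "BinaryMask",
    "median_filter_iterated",
    "otsu_threshold",
    "segment_channel",
    "spheroid_area",
    "normalized_area_series",
    "minimal_bounding_box",
    "extent",
]


@dataclass(frozen=True)
class FilterParams:
    """Iterated median filter settings: odd ``kernel_side`` (>= 3) and a
    pass count.  ``iterations=0`` disables filtering entirely."""

    kernel_side: int = 3
    iterations: int = 200

    def __post_init__(self) -> None:
        if self.kernel_side < 3 or self.kernel_side % 2 == 0:
            raise ValueError(f"kernel_side must be odd and >= 3, got {self.kernel_side}")
        if self.iterations < 0:
            raise ValueError(f"iterations must be >= 0, got {self.iterations}")


@dataclass(frozen=True)
class BinaryMask:
    """Foreground/background raster from segmenting one channel."""

    mask: np.ndarray            # 2-D bool
    channel_role: str
    threshold_used: int
    degenerate: bool = False    # constant channel: empty foreground by fiat

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def median_filter_iterated(chan: ChannelImage, params: FilterParams) -> ChannelImage:
    """Apply ``params.iterations`` passes of the 2-D median filter.

    Border pixels use reflect (symmetric) padding so bright structures near
    the frame are not eroded by an artificial dark margin.  Iteration stops
    early once a pass leaves the image unchanged — the image is then a fixed
    point of the filter and further passes are no-ops, so the result is
    bit-identical to running the full count.
    """
    arr = chan.intensities
    k = params.kernel_side
    if arr.shape[0] < k or arr.shape[1] < k:
        raise DegenerateInputError(
            f"image shape {arr.shape} smaller than {k}x{k} median kernel"
        )
    for _ in range(params.iterations):
        nxt = ndi.median_filter(arr, size=k, mode="reflect")
        if np.array_equal(nxt, arr):
            break
        arr = nxt
    return ChannelImage(arr, chan.channel_role)


def otsu_threshold(chan: ChannelImage) -> int:
    """Otsu's global threshold on the 8-bit histogram.

    Returns the threshold ``t`` in [0, 255] minimising the pixel-weighted
    within-class variance of the split (<= t) vs (> t); when several
    thresholds tie, the smallest is returned.  Foreground is defined
    downstream as intensity strictly greater than ``t``.
    """
    arr = np.asarray(chan.intensities)
    if arr.size == 0:
        raise DegenerateInputError("cannot threshold an empty image")
    hist = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    # cumulative count / sum / sum-of-squares for the low class at each t
    vals = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    s0 = np.cumsum(hist * vals)
    q0 = np.cumsum(hist * vals * vals)
    w1 = n - w0
    s1 = s0[-1] - s0
    q1 = q0[-1] - q0
    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = np.where(w0 > 0, q0 / np.maximum(w0, 1) - (s0 / np.maximum(w0, 1)) ** 2, 0.0)
        var1 = np.where(w1 > 0, q1 / np.maximum(w1, 1) - (s1 / np.maximum(w1, 1)) ** 2, 0.0)
    within = (w0 * var0 + w1 * var1) / n
    return int(np.argmin(within))


def segment_channel(chan: ChannelImage, params: FilterParams) -> BinaryMask:
    """Median-filter then Otsu-threshold one channel into a binary mask.

    A constant (blank-well) channel is degenerate: the mask is empty and
    flagged rather than raising, since area 0 is a meaningful observation.
    """
    filtered = median_filter_iterated(chan, params)
    arr = filtered.intensities
    lo, hi = int(arr.min()), int(arr.max())
    if lo == hi:
        return BinaryMask(
            mask=np.zeros(arr.shape, dtype=bool),
            channel_role=chan.channel_role,
            threshold_used=lo,
            degenerate=True,
        )
    t = otsu_threshold(filtered)
    return BinaryMask(mask=arr > t, channel_role=chan.channel_role, threshold_used=t)


def spheroid_area(mask: BinaryMask) -> int:
    """Foreground pixel count."""
    return int(np.count_nonzero(mask.mask))


def normalized_area_series(
    areas: Mapping[float, int], reference_time: float = 24.0
) -> dict[float, float]:
    """Divide each time point's area by the area at the reference time."""
    if reference_time not in areas:
        raise NormalisationError(
            f"reference time {reference_time} h missing from area series"
        )
    ref = areas[reference_time]
    if ref <= 0:
        raise NormalisationError(
            f"area at reference time {reference_time} h is {ref}; cannot normalise"
        )
    return {t: a / ref for t, a in areas.items()}


def minimal_bounding_box(mask: BinaryMask) -> tuple[int, int, int, int]:
    """Tight axis-aligned box over ALL foreground pixels, inclusive bounds.

    Disconnected components are unioned — the box spans every fragment.
    """
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise NoForegroundError("bounding box of an empty mask is undefined")
    return int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())


def extent(mask: BinaryMask) -> float:
    """Spheroid area over minimal-bounding-box area; in (0, 1]."""
    r0, c0, r1, c1 = minimal_bounding_box(mask)
    box = (r1 - r0 + 1) * (c1 - c0 + 1)
    return spheroid_area(mask) / box
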
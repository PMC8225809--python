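"""Segmentation-based trafficking index (TIS).

TIS controls for red-channel bleed-through from tumour cells by only looking
at pixels that segment as both tumour (green channel) and immune (red
channel): over that intersection it averages the red/green intensity ratio.
Red signal that never enters the tumour mask — immune cells sitting outside
the spheroid — cannot move the index.  The ratio uses the raw channel
intensities; the iterated-median-filtered images are used only to build the
masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ImageFormatError
from .io import ChannelImage
from .segmentation import BinaryMask, FilterParams, segment_channel

__all__ = ["TISResult", "compute_tis", "tis_per_pixel_map"]

#: floor for the green denominator; intersection pixels passed the green
#: Otsu threshold so raw green is rarely 0, but the guard keeps the ratio
#: finite and bounded by the red intensity.
GREEN_EPS = 1.0


@dataclass(frozen=True)
class TISResult:
    """TIS plus the region sizes that went into it.

    ``tis`` averages red/green over the tumour-immune mask intersection
    (zero when the intersection is empty).  ``tis_tumour_norm`` divides the
    same ratio sum by the tumour-mask size instead — the alternative reading
    of the normaliser — and is reported alongside.
    """

    tis: float
    tis_tumour_norm: float
    intersection_pixels: int
    tumour_pixels: int
    immune_pixels: int


def _masks(
    red: ChannelImage,
    green: ChannelImage,
    params: FilterParams,
    tumour_mask: BinaryMask | None,
    immune_mask: BinaryMask | None,
) -> tuple[BinaryMask, BinaryMask]:
    if red.shape != green.shape:
        raise ImageFormatError(
            f"red shape {red.shape} != green shape {green.shape}"
        )
    if tumour_mask is None:
        tumour_mask = segment_channel(green, params)
    if immune_mask is None:
        immune_mask = segment_channel(red, params)
    if tumour_mask.shape != red.shape or immune_mask.shape != red.shape:
        raise ImageFormatError("mask shapes do not match the channel images")
    return tumour_mask, immune_mask


def compute_tis(
    red: ChannelImage,
    green: ChannelImage,
    params: FilterParams = FilterParams(),
    *,
    tumour_mask: BinaryMask | None = None,
    immune_mask: BinaryMask | None = None,
) -> TISResult:
    """Compute TIS from the two channels.

    Both channels are segmented with the same filter settings as the area
    pipeline (pass precomputed masks to skip re-segmentation).  With
    intersection ``I``::

        TIS = (1 / |I|) * sum_{p in I} red(p) / max(green(p), 1)

    and ``TIS = 0`` when ``I`` is empty.
    """
    tmask, imask = _masks(red, green, params, tumour_mask, immune_mask)
    inter = tmask.mask & imask.mask
    n_inter = int(np.count_nonzero(inter))
    n_tum = int(np.count_nonzero(tmask.mask))
    n_imm = int(np.count_nonzero(imask.mask))
    if n_inter == 0:
        return TISResult(0.0, 0.0, 0, n_tum, n_imm)
    r = red.intensities[inter].astype(np.float64)
    g = np.maximum(green.intensities[inter].astype(np.float64), GREEN_EPS)
    total = float(np.sum(r / g))
    return TISResult(
        tis=total / n_inter,
        tis_tumour_norm=total / n_tum if n_tum else 0.0,
        intersection_pixels=n_inter,
        tumour_pixels=n_tum,
        immune_pixels=n_imm,
    )


def tis_per_pixel_map(
    red: ChannelImage,
    green: ChannelImage,
    params: FilterParams = FilterParams(),
    *,
    tumour_mask: BinaryMask | None = None,
    immune_mask: BinaryMask | None = None,
) -> np.ndarray:
    """Per-pixel red/green ratio on the intersection, 0 elsewhere.

    The mean of the map over its nonzero support equals :func:`compute_tis`
    (when the intersection is non-empty); useful as a QC overlay showing
    where the trafficking signal lives.
    """
    tmask, imask = _masks(red, green, params, tumour_mask, immune_mask)
    inter = tmask.mask & imask.mask
    out = np.zeros(red.shape, dtype=np.float64)
    if inter.any():
        r = red.intensities[inter].astype(np.float64)
        g = np.maximum(green.intensities[inter].astype(np.float64), GREEN_EPS)
        out[inter] = r / g
    return out
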
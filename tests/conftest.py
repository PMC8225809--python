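"""Shared fixtures and independent oracles for the spherotrack suite."""

from __future__ import annotations

import numpy as np
import pytest

from spherotrack import ChannelImage, RGBImage


# ---------------------------------------------------------------------------
# independent oracles (kept naive on purpose; they never share code with the
# implementation paths they check)
# ---------------------------------------------------------------------------

def otsu_oracle(arr: np.ndarray) -> int:
    """Exhaustive scan of all 256 thresholds minimising within-class
    variance of the (<= t) / (> t) split; smallest minimiser on ties."""
    flat = np.asarray(arr, dtype=np.float64).ravel()
    n = flat.size
    best_t, best_v = 0, np.inf
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        v = 0.0
        if lo.size:
            v += lo.size * lo.var()
        if hi.size:
            v += hi.size * hi.var()
        v /= n
        if v < best_v - 1e-12:
            best_v, best_t = v, t
    return best_t


def median_oracle(arr: np.ndarray, kernel: int = 3, iterations: int = 10_000) -> np.ndarray:
    """Naive per-pixel median loop with symmetric padding, run to a fixed
    point (or the iteration cap)."""
    arr = np.asarray(arr)
    m = kernel // 2
    for _ in range(iterations):
        padded = np.pad(arr, m, mode="symmetric")
        out = np.empty_like(arr)
        for r in range(arr.shape[0]):
            for c in range(arr.shape[1]):
                out[r, c] = np.median(padded[r : r + kernel, c : c + kernel])
        if np.array_equal(out, arr):
            return out
        arr = out
    return arr


def tic_oracle(classes: np.ndarray, window: int = 11) -> tuple[int, int]:
    """Brute-force (immune_in_tumour, cancer_in_tumour) counts: for every
    interior pixel, tally the window classes excluding the centre and ask
    for a strict tumour plurality."""
    from spherotrack.tic import IMMUNE, ROLES, TUMOUR

    h, w = classes.shape
    m = window // 2
    immune_in = cancer_in = 0
    for r in range(m, h - m):
        for c in range(m, w - m):
            block = classes[r - m : r + m + 1, c - m : c + m + 1]
            counts = np.bincount(block.ravel(), minlength=len(ROLES)).astype(int)
            counts[classes[r, c]] -= 1
            top = counts.max()
            if counts[TUMOUR] == top and (counts == top).sum() == 1:
                if classes[r, c] == IMMUNE:
                    immune_in += 1
                elif classes[r, c] == TUMOUR:
                    cancer_in += 1
    return immune_in, cancer_in


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_tis_fixture() -> tuple[ChannelImage, ChannelImage]:
    """6x6 image: 4x4 green square (200) containing a 2x2 red patch
    (red 100, green 200 there; red 0 elsewhere)."""
    green = np.zeros((6, 6), dtype=np.uint8)
    green[1:5, 1:5] = 200
    red = np.zeros((6, 6), dtype=np.uint8)
    red[2:4, 2:4] = 100
    return ChannelImage(red, "red"), ChannelImage(green, "green")


@pytest.fixture
def tis_fixture() -> tuple[ChannelImage, ChannelImage]:
    return make_tis_fixture()


@pytest.fixture
def rgb_random() -> RGBImage:
    rng = np.random.default_rng(42)
    return RGBImage(rng.integers(0, 256, size=(16, 20, 3), dtype=np.uint8))
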
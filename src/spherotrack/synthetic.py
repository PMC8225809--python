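"""Synthetic two-channel co-culture images with known ground truth.

The generator emulates the salient features of confocal maximum projections
of the spheroid/splenocyte co-culture: a roughly disk-shaped green spheroid
(optionally fragmented into several masses or hollowed out), small red
immune-cell disks scattered inside and outside the spheroid, substantial
red-channel bleed-through within tumour pixels, a sprinkling of
colour-saturated pixels, and dark Gaussian background noise.  Every image
comes with its ground truth (tumour mask, immune positions with
inside/outside labels, per-pixel class labels), so each analysis stage can
be validated without microscopy data.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so any image of a series can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateInputError, LayoutError
from .io import ExperimentLayout, LayoutEntry, RGBImage
from .tic import BACKGROUND, IMMUNE, SATURATED, TUMOUR

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "generate_coculture_image",
    "generate_timeseries",
    "write_synthetic_experiment",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the co-culture image generator.

    Intensity levels are mean 8-bit values; each rendered pixel gets
    Gaussian jitter of ``intensity_jitter_sd`` before clipping to [0, 255].
    ``infiltration_fraction`` is realised exactly: round(f * n) immune cells
    are placed inside the spheroid, the rest well outside it.
    """

    image_size: int = 256
    spheroid_radius: float = 55.0
    fragmentation: int = 1          # number of tumour masses
    hollow_fraction: float = 0.0    # hole radius / fragment radius
    n_immune_cells: int = 40
    infiltration_fraction: float = 0.3
    immune_cell_radius: float = 3.0
    tumour_green_level: float = 180.0
    tumour_red_bleedthrough: float = 60.0
    immune_red_level: float = 220.0
    immune_green_level: float = 30.0
    saturated_fraction: float = 0.02  # of tumour pixels driven to (255, 255)
    background_level: float = 10.0
    background_noise_sd: float = 8.0
    intensity_jitter_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hollow_fraction", "infiltration_fraction", "saturated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spheroid_radius < 1 or self.immune_cell_radius < 1:
            raise ValueError("radii must be >= 1 pixel")
        if self.fragmentation < 1:
            raise ValueError("fragmentation must be >= 1")
        for name in (
            "tumour_green_level", "tumour_red_bleedthrough",
            "immune_red_level", "immune_green_level", "background_level",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name} must be in [0, 255], got {v}")


@dataclass(frozen=True)
class GroundTruth:
    """Generating truth for one synthetic image (the test oracle)."""

    tumour_mask: np.ndarray                       # bool, pre-saturation
    immune_positions: tuple[tuple[int, int, bool], ...]  # (row, col, inside)
    true_infiltration_fraction: float
    class_labels: np.ndarray                      # uint8 codes into ROLES

    @property
    def tumour_area(self) -> int:
        return int(np.count_nonzero(self.tumour_mask))


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _tumour_mask(p: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    size = p.image_size
    shape = (size, size)
    c = (size - 1) / 2.0
    mask = np.zeros(shape, dtype=bool)
    if p.fragmentation == 1:
        centers = [(c, c)]
        frag_r = p.spheroid_radius
    else:
        # fragments of equal total area on a jittered ring around the centre;
        # the ring is wide enough that neighbouring fragments stay disjoint
        frag_r = p.spheroid_radius / np.sqrt(p.fragmentation)
        ring = max(
            0.55 * p.spheroid_radius,
            1.15 * frag_r / np.sin(np.pi / p.fragmentation),
        )
        angles = 2 * np.pi * (np.arange(p.fragmentation) / p.fragmentation)
        angles = angles + rng.uniform(0, 2 * np.pi)
        centers = [
            (
                c + ring * np.sin(a) + rng.normal(0, 0.05 * p.spheroid_radius),
                c + ring * np.cos(a) + rng.normal(0, 0.05 * p.spheroid_radius),
            )
            for a in angles
        ]
    for ctr in centers:
        frag = _disk(shape, ctr, frag_r)
        if p.hollow_fraction > 0:
            frag &= ~_disk(shape, ctr, p.hollow_fraction * frag_r)
        mask |= frag
    return mask


def _place_immune(
    p: SyntheticParams, tumour: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int, bool]]:
    """Choose immune-cell centres: exact count inside, rest outside."""
    n_inside = int(round(p.infiltration_fraction * p.n_immune_cells))
    n_outside = p.n_immune_cells - n_inside
    r = p.immune_cell_radius
    positions: list[tuple[int, int, bool]] = []

    if n_inside > 0:
        # cells must fit wholly inside the tumour mask
        dist_in = ndi.distance_transform_edt(tumour)
        rows, cols = np.nonzero(dist_in > r)
        if rows.size == 0:
            raise DegenerateInputError(
                "immune cell radius too large: no interior placement fits the spheroid"
            )
        idx = rng.choice(rows.size, size=n_inside, replace=rows.size < n_inside)
        positions += [(int(rows[i]), int(cols[i]), True) for i in idx]

    if n_outside > 0:
        # clearly non-infiltrated: whole disk off the (slightly dilated) tumour
        dist_out = ndi.distance_transform_edt(~tumour)
        ok = dist_out > r + 2
        m = int(np.ceil(r)) + 1
        border = np.zeros_like(ok)
        border[m:-m, m:-m] = True
        ok &= border
        rows, cols = np.nonzero(ok)
        if rows.size == 0:
            raise DegenerateInputError("no room outside the spheroid for immune cells")
        idx = rng.choice(rows.size, size=n_outside, replace=rows.size < n_outside)
        positions += [(int(rows[i]), int(cols[i]), False) for i in idx]
    return positions


def generate_coculture_image(params: SyntheticParams) -> tuple[RGBImage, GroundTruth]:
    """Render one synthetic co-culture image plus its ground truth.

    Deterministic under ``params.seed``: the same parameters always yield
    bit-identical pixels.
    """
    p = params
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    shape = (p.image_size, p.image_size)

    tumour = _tumour_mask(p, rng)
    positions = _place_immune(p, tumour, rng) if p.n_immune_cells > 0 else []

    red = rng.normal(p.background_level, p.background_noise_sd, shape)
    green = rng.normal(p.background_level, p.background_noise_sd, shape)
    blue = rng.normal(p.background_level, p.background_noise_sd, shape)
    jit = p.intensity_jitter_sd

    n_tum = int(np.count_nonzero(tumour))
    green[tumour] = rng.normal(p.tumour_green_level, jit, n_tum)
    red[tumour] = rng.normal(p.tumour_red_bleedthrough, jit, n_tum)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[tumour] = TUMOUR

    immune_mask = np.zeros(shape, dtype=bool)
    for r0, c0, _inside in positions:
        immune_mask |= _disk(shape, (r0, c0), p.immune_cell_radius)
    n_imm = int(np.count_nonzero(immune_mask))
    if n_imm:
        red[immune_mask] = rng.normal(p.immune_red_level, jit, n_imm)
        green[immune_mask] = rng.normal(p.immune_green_level, jit, n_imm)
        labels[immune_mask] = IMMUNE

    if p.saturated_fraction > 0 and n_tum > 0:
        tr, tc = np.nonzero(tumour & ~immune_mask)
        n_sat = int(round(p.saturated_fraction * n_tum))
        n_sat = min(n_sat, tr.size)
        if n_sat:
            idx = rng.choice(tr.size, size=n_sat, replace=False)
            red[tr[idx], tc[idx]] = 255.0
            green[tr[idx], tc[idx]] = 255.0
            labels[tr[idx], tc[idx]] = SATURATED

    pixels = np.stack(
        [np.clip(np.round(ch), 0, 255).astype(np.uint8) for ch in (red, green, blue)],
        axis=2,
    )
    n_in = sum(1 for _, _, inside in positions if inside)
    truth = GroundTruth(
        tumour_mask=tumour,
        immune_positions=tuple(positions),
        true_infiltration_fraction=(n_in / len(positions)) if positions else 0.0,
        class_labels=labels,
    )
    return RGBImage(pixels=pixels, source_path=f"<synthetic seed={p.seed}>"), truth


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_timeseries(
    params: SyntheticParams, growth_factors: Mapping[float, float]
) -> dict[float, tuple[RGBImage, GroundTruth]]:
    """One image per time point with ground-truth area following growth.

    The spheroid radius at each time is the base radius scaled by
    sqrt(growth factor), so true pixel-area ratios equal the factors up to
    rasterisation error.  Each time point gets its own child seed.
    """
    if not growth_factors:
        raise LayoutError("growth_factors must not be empty")
    times = sorted(growth_factors)
    seeds = _child_seeds(params.seed, len(times))
    out: dict[float, tuple[RGBImage, GroundTruth]] = {}
    for t, s in zip(times, seeds):
        p_t = replace(
            params,
            spheroid_radius=params.spheroid_radius * float(np.sqrt(growth_factors[t])),
            seed=s,
        )
        out[t] = generate_coculture_image(p_t)
    return out


def write_synthetic_experiment(
    out_dir: str | Path,
    groups: Sequence[str],
    times_h: Sequence[float],
    base_params: SyntheticParams,
    *,
    growth_factors: Mapping[float, float] | None = None,
    infiltration_by_group: Mapping[str, float] | None = None,
    reference_time: float = 24.0,
    seed: int = 0,
) -> tuple[ExperimentLayout, dict[str, GroundTruth]]:
    """Render a full group x time experiment to PNG files plus a layout.

    Each (group, time) cell gets one image.  Per-group infiltration
    fractions model treatment effects; per-time growth factors (relative to
    the reference time) model spheroid growth.  Returns the resolved layout
    and the ground truth keyed by file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(seed, len(groups) * len(times_h))
    entries: list[LayoutEntry] = []
    truths: dict[str, GroundTruth] = {}
    i = 0
    for group in groups:
        for t in sorted(times_h):
            p = base_params
            if infiltration_by_group is not None:
                p = replace(p, infiltration_fraction=infiltration_by_group[group])
            if growth_factors is not None:
                p = replace(
                    p,
                    spheroid_radius=base_params.spheroid_radius
                    * float(np.sqrt(growth_factors[t])),
                )
            p = replace(p, seed=seeds[i])
            i += 1
            img, truth = generate_coculture_image(p)
            fname = out_dir / f"{group}_t{int(t):03d}.png"
            iio.imwrite(fname, img.pixels)
            entries.append(LayoutEntry(group=group, time_h=float(t), path=str(fname)))
            truths[str(fname)] = truth
    layout = ExperimentLayout(entries=tuple(entries), reference_time=reference_time)
    return layout, truths
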
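"""Loading confocal co-culture images and resolving experiment layouts.

Images are RGB maximum projections of the two-channel co-culture: the green
channel carries the DiO-stained tumour spheroid, the red channel the
DiI-stained immune cells.  Everything downstream works on 8-bit intensities;
deeper images are rescaled to [0, 255] at load time.  The blue plane is
carried in :class:`RGBImage` but discarded by :func:`split_channels`.

Coordinates are row-major, 0-based, origin at the top-left.
"""

from __future__ import annotations

import glob as _glob
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import ImageFormatError, ImageInputError, LayoutError

__all__ = [
    "RGBImage",
    "ChannelImage",
    "LayoutEntry",
    "ExperimentLayout",
    "load_rgb_image",
    "split_channels",
    "resolve_layout",
    "load_layout_config",
]


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB raster plus provenance.

    ``pixels`` has shape ``(height, width, 3)`` and dtype ``uint8``.
    """

    pixels: np.ndarray
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"RGBImage needs a (H, W, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("image must be at least 1x1")
        if px.dtype != np.uint8:
            raise ImageFormatError("RGBImage pixels must be uint8 in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ChannelImage:
    """One colour plane of an :class:`RGBImage` as a grey image.

    ``channel_role`` is ``"red"`` (immune cells) or ``"green"`` (tumour).
    """

    intensities: np.ndarray
    channel_role: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise ImageFormatError(
                f"ChannelImage needs a 2-D array, got shape {arr.shape}"
            )
        if self.channel_role not in ("red", "green"):
            raise ValueError(f"channel_role must be 'red' or 'green', got {self.channel_role!r}")
        if arr.dtype != np.uint8:
            arr = np.asarray(arr, dtype=np.uint8)
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


def load_rgb_image(path: str | Path) -> RGBImage:
    """Read an RGB(A) PNG/TIFF and normalise it to 8 bits.

    Integer images deeper than 8 bits are rescaled by linear division of the
    full bit range (65535 -> 255 for 16-bit); float images are assumed to lie
    in [0, 1].  Alpha planes are discarded.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise ImageInputError(f"cannot read image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 2:
        raise ImageFormatError(
            f"{path} is a single-plane (grayscale) image; an RGB image is required"
        )
    if raw.ndim != 3 or raw.shape[2] < 3:
        raise ImageFormatError(f"{path}: unsupported image shape {raw.shape}")
    rgb = raw[:, :, :3]
    if rgb.dtype == np.uint8:
        px = rgb
    elif np.issubdtype(rgb.dtype, np.integer):
        full = np.iinfo(rgb.dtype).max
        px = np.round(rgb.astype(np.float64) * (255.0 / full)).astype(np.uint8)
    elif np.issubdtype(rgb.dtype, np.floating):
        px = np.round(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)
    else:
        raise ImageFormatError(f"{path}: unsupported dtype {rgb.dtype}")
    return RGBImage(pixels=px, source_path=str(path))


def split_channels(img: RGBImage) -> tuple[ChannelImage, ChannelImage]:
    """Split an RGB image into its red and green grey images (blue dropped)."""
    red = ChannelImage(img.pixels[:, :, 0].copy(), "red")
    green = ChannelImage(img.pixels[:, :, 1].copy(), "green")
    return red, green


@dataclass(frozen=True)
class LayoutEntry:
    group: str
    time_h: float
    path: str
    replicate: int = 0


@dataclass(frozen=True)
class ExperimentLayout:
    """Mapping of (treatment group, imaging time) cells to image files."""

    entries: tuple[LayoutEntry, ...]
    reference_time: float = 24.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.group, None)
        return tuple(seen)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(sorted({e.time_h for e in self.entries}))

    def cell(self, group: str, time_h: float) -> tuple[LayoutEntry, ...]:
        return tuple(
            e for e in self.entries if e.group == group and e.time_h == time_h
        )

    def missing_reference(self) -> tuple[str, ...]:
        """Groups with no image at the reference time."""
        return tuple(
            g for g in self.groups if not self.cell(g, self.reference_time)
        )


def resolve_layout(config: Mapping) -> ExperimentLayout:
    """Build an :class:`ExperimentLayout` from a layout description.

    ``config`` either lists explicit ``entries`` (group, time_h, path) or
    gives ``groups``, ``times_h`` and a ``path_pattern`` containing
    ``{group}`` / ``{time}`` placeholders (glob wildcards allowed).  Every
    declared (group, time) cell must match at least one existing file.
    Entries are sorted by (group order as declared, time, path) and replicate
    indices are assigned within each cell.
    """
    reference_time = float(config.get("reference_time_h", 24.0))
    raw_entries: list[tuple[str, float, str]] = []
    if "entries" in config:
        for item in config["entries"]:
            if isinstance(item, Mapping):
                raw_entries.append(
                    (str(item["group"]), float(item["time_h"]), str(item["path"]))
                )
            else:
                g, t, p = item
                raw_entries.append((str(g), float(t), str(p)))
        for g, t, p in raw_entries:
            if not Path(p).exists():
                raise LayoutError(f"layout entry ({g}, {t} h): file not found: {p}")
        declared_groups = list(dict.fromkeys(g for g, _, _ in raw_entries))
    else:
        groups = [str(g) for g in config["groups"]]
        times = [float(t) for t in config["times_h"]]
        pattern = str(config["path_pattern"])
        for g in groups:
            for t in times:
                pat = pattern.format(group=g, time=_format_time(t))
                matches = sorted(_glob.glob(pat))
                matches = [m for m in matches if Path(m).is_file()]
                if not matches:
                    raise LayoutError(
                        f"no image matches pattern {pat!r} for group {g!r} at {t} h"
                    )
                raw_entries.extend((g, t, m) for m in matches)
        declared_groups = groups

    order = {g: i for i, g in enumerate(declared_groups)}
    raw_entries.sort(key=lambda e: (order[e[0]], e[1], e[2]))
    entries: list[LayoutEntry] = []
    counter: dict[tuple[str, float], int] = {}
    for g, t, p in raw_entries:
        rep = counter.get((g, t), 0)
        counter[(g, t)] = rep + 1
        entries.append(LayoutEntry(group=g, time_h=t, path=p, replicate=rep))
    return ExperimentLayout(entries=tuple(entries), reference_time=reference_time)


def _format_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def load_layout_config(path: str | Path) -> ExperimentLayout:
    """Load a YAML or JSON layout file and resolve it.

    Relative ``path_pattern``/entry paths are taken relative to the config
    file's directory.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise LayoutError(f"{path}: layout config must be a mapping")
    config = dict(config)
    base = path.parent
    if "path_pattern" in config and not Path(config["path_pattern"]).is_absolute():
        config["path_pattern"] = str(base / config["path_pattern"])
    if "entries" in config:
        fixed = []
        for item in config["entries"]:
            item = dict(item) if isinstance(item, Mapping) else {
                "group": item[0], "time_h": item[1], "path": item[2]
            }
            if not Path(item["path"]).is_absolute():
                item["path"] = str(base / item["path"])
            fixed.append(item)
        config["entries"] = fixed
    return resolve_layout(config)
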
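"""Batch analysis of a whole co-culture experiment into a tidy table.

One row per image: pixel area, area normalised to the 24 h reference of the
same well, extent, TIS and TIC, plus group/time metadata and any degeneracy
flags.  A per-group mean +/- SEM summary is computed alongside; downstream
group comparisons (ANOVA etc.) are deliberately out of scope — the CSV is
the hand-off point.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import NoForegroundError, SpherotrackError
from .io import ChannelImage, ExperimentLayout, load_rgb_image, split_channels
from .segmentation import (
    FilterParams,
    extent,
    segment_channel,
    spheroid_area,
)
from .tic import PixelClassifier, classify_pixels, compute_tic
from .tis import compute_tis

__all__ = ["SpheroidRecord", "analyze_image", "analyze_experiment", "write_records_csv"]

logger = logging.getLogger(__name__)

MEASURE_COLUMNS = ["area_px", "normalized_area", "extent", "tis", "tic"]

CSV_COLUMNS = [
    "group", "time_h", "replicate", "area_px", "normalized_area",
    "extent", "tis", "tic", "tic_excluded_border", "degenerate_flags",
]


@dataclass
class SpheroidRecord:
    """Per-image measurement row."""

    group: str = ""
    time_h: float = float("nan")
    replicate: int = 0
    area_px: int = 0
    normalized_area: float = float("nan")
    extent: float = float("nan")
    tis: float = 0.0
    tic: float = 0.0
    tic_excluded_border: int = 0
    degenerate_flags: str = ""


def analyze_image(
    red: ChannelImage,
    green: ChannelImage,
    clf: PixelClassifier | None = None,
    params: FilterParams = FilterParams(),
    window: int = 11,
) -> SpheroidRecord:
    """Run every measurement on one image; degenerate cases flag, not fail.

    Segmentation runs once per channel and is shared between the area and
    TIS computations.  ``clf`` may be ``None``, in which case TIC is
    reported as 0 with a flag.
    """
    flags: list[str] = []
    tumour_mask = segment_channel(green, params)
    immune_mask = segment_channel(red, params)
    if tumour_mask.degenerate:
        flags.append("green_degenerate")
    if immune_mask.degenerate:
        flags.append("red_degenerate")

    area = spheroid_area(tumour_mask)
    try:
        ext = extent(tumour_mask)
    except NoForegroundError:
        ext = float("nan")
        flags.append("no_foreground")

    tis_res = compute_tis(
        red, green, params, tumour_mask=tumour_mask, immune_mask=immune_mask
    )

    tic_val, tic_border = 0.0, 0
    if clf is not None:
        cmap = classify_pixels(clf, red, green)
        tic_res = compute_tic(cmap, window=window)
        tic_val, tic_border = tic_res.tic, tic_res.excluded_border
        if tic_res.degenerate:
            flags.append("tic_zero_denominator")
    else:
        flags.append("no_classifier")

    return SpheroidRecord(
        area_px=area,
        extent=ext,
        tis=tis_res.tis,
        tic=tic_val,
        tic_excluded_border=tic_border,
        degenerate_flags=";".join(flags),
    )


def analyze_experiment(
    layout: ExperimentLayout,
    clf: PixelClassifier | None = None,
    params: FilterParams = FilterParams(),
    window: int = 11,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse every layout entry; returns (records, per-group summary).

    Rows are ordered by (group as declared, time, replicate).  The
    normalised area divides each well's area by the same well's area at the
    layout's reference time; wells with a missing or zero-area reference are
    flagged and left NaN, and the run continues.  The summary holds mean and
    SEM (SD with n-1 denominator over sqrt(n)) per (group, time).
    """
    records: list[SpheroidRecord] = []
    for entry in layout.entries:
        try:
            red, green = split_channels(load_rgb_image(entry.path))
            rec = analyze_image(red, green, clf, params, window)
        except SpherotrackError as exc:
            logger.error("skipping %s: %s", entry.path, exc)
            continue
        rec.group, rec.time_h, rec.replicate = entry.group, entry.time_h, entry.replicate
        logger.info(
            "analyzed %s: area=%d extent=%.4f tis=%.4f tic=%.4f flags=%r",
            entry.path, rec.area_px, rec.extent, rec.tis, rec.tic,
            rec.degenerate_flags,
        )
        records.append(rec)

    df = pd.DataFrame([asdict(r) for r in records], columns=CSV_COLUMNS)

    # per-well normalisation against the reference time
    ref_t = layout.reference_time
    for (group, rep), idx in df.groupby(["group", "replicate"]).groups.items():
        sub = df.loc[idx]
        ref_rows = sub[sub["time_h"] == ref_t]
        if ref_rows.empty or int(ref_rows.iloc[0]["area_px"]) <= 0:
            df.loc[idx, "degenerate_flags"] = df.loc[idx, "degenerate_flags"].apply(
                lambda f: ";".join(x for x in (f, "no_reference_area") if x)
            )
            continue
        ref_area = float(ref_rows.iloc[0]["area_px"])
        df.loc[idx, "normalized_area"] = df.loc[idx, "area_px"] / ref_area

    group_order = {g: i for i, g in enumerate(layout.groups)}
    df = df.sort_values(
        by=["group", "time_h", "replicate"],
        key=lambda col: col.map(group_order) if col.name == "group" else col,
        kind="stable",
    ).reset_index(drop=True)

    summary = (
        df.groupby(["group", "time_h"], sort=True)[MEASURE_COLUMNS]
        .agg(["mean", "sem"])
    )
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary = summary.reset_index()
    return df, summary


def write_records_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the record table with fixed float formatting.

    Formatting is pinned so a re-run over unchanged inputs produces
    byte-identical output.
    """
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
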
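"""Track filtering, windowed smoothing, per-track standardization, anomaly
masking, and unit conversion.

The fluorescence pipeline order is fixed: mask -> smooth -> standardize.
Smoothing is a centered moving average truncated at track ends; masked frames
contribute nothing to any window mean and stay missing downstream.
Standardization mean-centers each track and divides by its own sample
standard deviation, so standardized series are in per-track s.d. units.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from apicaltrack.geometry import orientation
from apicaltrack.tables_io import Dataset, EmbryoConfig

__all__ = [
    "filter_tracks",
    "smooth_series",
    "standardize_series",
    "mask_frames",
    "to_microns",
    "preprocess_dataset",
    "CELL_FLUOR_COLUMNS",
    "JUNCTION_FLUOR_COLUMNS",
]

log = logging.getLogger(__name__)

# Raw fluorescence columns subject to anomaly masking and smoothing.
CELL_FLUOR_COLUMNS = [
    "medial_actin",
    "junctional_actin",
    "medial_Ncadherin",
    "junctional_Ncadherin",
    "medial_memBFP",
    "junctional_memBFP",
]
# Columns that additionally get a *_standardized companion (the membrane-BFP
# lineage tracer is thresholded, never standardized).
CELL_STANDARDIZED = [
    "apical_area",
    "medial_actin",
    "junctional_actin",
    "medial_Ncadherin",
    "junctional_Ncadherin",
]
JUNCTION_FLUOR_COLUMNS = ["actin", "Ncadherin"]

DEFAULT_MIN_CELL_FRAMES = 30
DEFAULT_MIN_JUNCTION_FRAMES = 15
DEFAULT_WINDOW = 7


def filter_tracks(
    dataset: Dataset,
    min_cell_frames: int = DEFAULT_MIN_CELL_FRAMES,
    min_junction_frames: int = DEFAULT_MIN_JUNCTION_FRAMES,
) -> Dataset:
    """Discard short tracks: cells shorter than ``min_cell_frames`` frames and
    junctions shorter than ``min_junction_frames`` (boundary lengths kept)."""
    out = dataset.copy()
    for attr, id_col, minlen in [
        ("cells", "track_id_cells", min_cell_frames),
        ("junctions", "track_id_junctions", min_junction_frames),
    ]:
        df = getattr(out, attr)
        if df is None or df.empty:
            continue
        sizes = df.groupby(["movie", id_col], sort=False)["minute"].transform("size")
        kept = df[sizes >= minlen].reset_index(drop=True)
        n_tracks_before = df.groupby(["movie", id_col], sort=False).ngroups
        n_tracks_after = (
            kept.groupby(["movie", id_col], sort=False).ngroups if not kept.empty else 0
        )
        log.info(
            "filter_tracks: %s %d -> %d tracks (min %d frames)",
            attr, n_tracks_before, n_tracks_after, minlen,
        )
        setattr(out, attr, kept)
    return out


def smooth_series(values: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered moving average over ``window`` frames, truncated at the ends.

    Each frame's smoothed value is the mean of the usable (non-NaN) values in
    the centered window, so the window shrinks near track ends instead of
    dropping frames.  Frames that are themselves missing stay missing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    out = pd.Series(v).rolling(window, center=True, min_periods=1).mean().to_numpy()
    out[np.isnan(v)] = np.nan  # masked frames stay masked
    return out


def standardize_series(values: np.ndarray, ddof: int = 1):
    """Mean-center a track and divide by its sample standard deviation.

    Returns ``(standardized, degenerate)``: with fewer than two usable frames
    or zero spread the output is all-missing and ``degenerate`` is True.
    """
    v = np.asarray(values, dtype=float)
    usable = ~np.isnan(v)
    out = np.full_like(v, np.nan)
    if usable.sum() < 2:
        return out, True
    mean = v[usable].mean()
    sd = v[usable].std(ddof=ddof)
    if sd == 0:
        return out, True
    out[usable] = (v[usable] - mean) / sd
    return out, False


def mask_frames(dataset: Dataset, configs: Mapping[str, EmbryoConfig] | EmbryoConfig) -> Dataset:
    """Discard fluorescence values on configured frame ranges.

    Only intensity variables are masked; geometry (areas, lengths, vertices)
    is retained so cells remain tracked through the anomaly.
    """
    if isinstance(configs, EmbryoConfig):
        configs = {configs.movie: configs}
    out = dataset.copy()
    for attr, fluor in [("cells", CELL_FLUOR_COLUMNS),
                        ("junctions", JUNCTION_FLUOR_COLUMNS)]:
        df = getattr(out, attr)
        if df is None or df.empty:
            continue
        for movie, cfg in configs.items():
            for start, end in cfg.masked_frame_ranges:
                sel = (df["movie"] == movie) & df["minute"].between(start, end)
                n = int(sel.sum())
                if n:
                    cols = [c for c in fluor if c in df.columns]
                    df.loc[sel, cols] = np.nan
                    log.info("mask_frames: %s movie %s frames %d-%d: "
                             "%d rows masked", attr, movie, start, end, n)
    return out


def to_microns(value_px: float, kind: str, config: EmbryoConfig) -> float:
    """Convert a pixel measurement to microns: length × s, area × s²."""
    s = config.microns_per_pixel
    if s <= 0:
        raise ValueError("microns_per_pixel must be positive")
    if kind == "length":
        return value_px * s
    if kind == "area":
        return value_px * s * s
    raise ValueError(f"unknown kind {kind!r} (expected 'length' or 'area')")


def _per_track(df, id_col, col, func):
    """Apply ``func`` per (movie, track) over ``col``, preserving order."""
    return (
        df.groupby(["movie", id_col], sort=False, group_keys=False)[col]
        .transform(lambda s: func(s.to_numpy()))
    )


def preprocess_dataset(
    dataset: Dataset,
    configs: Mapping[str, EmbryoConfig],
    window: int = DEFAULT_WINDOW,
    min_cell_frames: int = DEFAULT_MIN_CELL_FRAMES,
    min_junction_frames: int = DEFAULT_MIN_JUNCTION_FRAMES,
) -> Dataset:
    """Run the full preprocessing pipeline on raw tracked tables.

    Order: filter short tracks -> mask anomaly frames -> smooth -> convert
    units / correct lengths / orient junctions -> standardize.  Fills every
    ``*_smoothed``/``*_smooth``, micron, corrected, standardized, and
    orientation column of the schema.
    """
    ds = filter_tracks(dataset, min_cell_frames, min_junction_frames)
    ds = mask_frames(ds, configs)
    sm = lambda a: smooth_series(a, window)
    std = lambda a: standardize_series(a)[0]

    cells = ds.cells
    if cells is not None and not cells.empty:
        cells = cells.sort_values(["movie", "track_id_cells", "minute"]).reset_index(drop=True)
        cells["apical_area_pixels_smoothed"] = _per_track(
            cells, "track_id_cells", "apical_area_pixels", sm)
        scale = cells["movie"].map(
            {m: c.microns_per_pixel for m, c in configs.items()}).astype(float)
        cells["apical_area_micron_smoothed"] = (
            cells["apical_area_pixels_smoothed"] * scale**2)
        cells["apical_area_standardized"] = _per_track(
            cells, "track_id_cells", "apical_area_pixels_smoothed", std)
        for col in CELL_FLUOR_COLUMNS:
            if col not in cells.columns:
                continue
            cells[f"{col}_smoothed"] = _per_track(cells, "track_id_cells", col, sm)
            if col.replace("medial_", "").replace("junctional_", "") != "memBFP":
                cells[f"{col}_standardized"] = _per_track(
                    cells, "track_id_cells", f"{col}_smoothed", std)
        ds.cells = cells

    jx = ds.junctions
    if jx is not None and not jx.empty:
        jx = jx.sort_values(["movie", "track_id_junctions", "minute"]).reset_index(drop=True)
        scale = jx["movie"].map(
            {m: c.microns_per_pixel for m, c in configs.items()}).astype(float)
        if "length_px" not in jx.columns or jx["length_px"].isna().all():
            jx["length_px"] = np.hypot(jx["vx_2_x"] - jx["vx_1_x"],
                                       jx["vx_2_y"] - jx["vx_1_y"])
        jx["length_micron"] = jx["length_px"] * scale
        dz = jx["delta_z_micron"].astype(float) if "delta_z_micron" in jx.columns \
            else pd.Series(0.0, index=jx.index)
        dz = dz.fillna(0.0)
        jx["length_corrected"] = np.hypot(jx["length_micron"], dz)
        jx["length_smooth"] = _per_track(jx, "track_id_junctions",
                                         "length_corrected", sm)
        jx["length_standardized"] = _per_track(jx, "track_id_junctions",
                                               "length_smooth", std)
        for col in JUNCTION_FLUOR_COLUMNS:
            if col not in jx.columns:
                continue
            jx[f"{col}_smooth"] = _per_track(jx, "track_id_junctions", col, sm)
            jx[f"{col}_standardized"] = _per_track(
                jx, "track_id_junctions", f"{col}_smooth", std)
        angles = jx["movie"].map(
            {m: c.ap_axis_angle_deg for m, c in configs.items()}).astype(float)
        jx["orientation"] = [
            orientation((x1, y1), (x2, y2), a)
            for x1, y1, x2, y2, a in zip(
                jx["vx_1_x"], jx["vx_1_y"], jx["vx_2_x"], jx["vx_2_y"], angles)
        ]
        ds.junctions = jx
    return ds
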
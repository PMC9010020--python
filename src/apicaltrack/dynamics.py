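"""Per-track delta statistics, summary tables, quadrant fractions, and
stable T1 neighbor-exchange detection.

The delta statistic of a standardized track is its final usable value minus
its first usable value — the net change in per-track s.d. units.  A stable
T1 transition is a loss of adjacency between one cell pair that persists for
at least ``k_stable`` frames, paired (within ±``pair_window`` frames) with a
persistent gain of adjacency between the orthogonal pair of common
neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from apicaltrack.genotype import AdjacencyFrame, classify_junction
from apicaltrack.tables_io import Dataset

__all__ = [
    "T1Event",
    "delta_stat",
    "summarize",
    "quadrant_fractions",
    "detect_t1",
]


@dataclass(frozen=True)
class T1Event:
    """One stable neighbor exchange: pair (a, b) loses contact, (c, d) gains."""

    losing_pair: tuple
    gaining_pair: tuple
    loss_frame: int
    gain_frame: int
    stable: bool = True


def delta_stat(values) -> float:
    """Last usable value minus first usable value of a series (NaN-aware)."""
    v = np.asarray(values, dtype=float)
    usable = v[~np.isnan(v)]
    if len(usable) < 2:
        return float("nan")
    return float(usable[-1] - usable[0])


def _first_last(values):
    v = np.asarray(values, dtype=float)
    usable = v[~np.isnan(v)]
    if len(usable) == 0:
        return float("nan"), float("nan")
    return float(usable[0]), float(usable[-1])


def summarize(dataset: Dataset, interface_flags: pd.DataFrame | None = None) -> Dataset:
    """Build the per-track summary tables from a preprocessed dataset.

    Cell summaries carry start/end smoothed micron areas, the five delta
    statistics, and the mosaic-interface flag; junction summaries carry the
    three junction deltas and the track-mean orientation.
    """
    out = dataset.copy()
    cells = dataset.cells
    if cells is not None and not cells.empty:
        rows = []
        for (movie, tid), grp in cells.groupby(["movie", "track_id_cells"],
                                               sort=False):
            start_um, end_um = _first_last(grp.get("apical_area_micron_smoothed"))
            crispr = grp["CRISPR"].dropna()
            rows.append({
                "region": grp["region"].iloc[0],
                "movie": movie,
                "track_id_cells": tid,
                "CRISPR": crispr.iloc[0] if len(crispr) else np.nan,
                "at_mosaic_interface": np.nan,
                "start_area_micron": start_um,
                "end_area_micron": end_um,
                "delta_apical_area": delta_stat(grp.get("apical_area_standardized")),
                "delta_medial_actin": delta_stat(grp.get("medial_actin_standardized")),
                "delta_junctional_actin": delta_stat(grp.get("junctional_actin_standardized")),
                "delta_medial_Ncadherin": delta_stat(grp.get("medial_Ncadherin_standardized")),
                "delta_junctional_Ncadherin": delta_stat(grp.get("junctional_Ncadherin_standardized")),
            })
        stats = pd.DataFrame(rows)
        if interface_flags is not None and not interface_flags.empty:
            stats = stats.drop(columns=["at_mosaic_interface"]).merge(
                interface_flags, on=["movie", "track_id_cells"], how="left")
            stats["at_mosaic_interface"] = stats["at_mosaic_interface"].fillna(False)
        out.cell_stats = stats

    jx = dataset.junctions
    if jx is not None and not jx.empty:
        rows = []
        for (movie, tid), grp in jx.groupby(["movie", "track_id_junctions"],
                                            sort=False):
            crispr = grp["CRISPR"].dropna()
            rows.append({
                "region": grp["region"].iloc[0],
                "movie": movie,
                "track_id_junctions": tid,
                "CRISPR": crispr.iloc[0] if len(crispr) else np.nan,
                "delta_length": delta_stat(grp.get("length_standardized")),
                "delta_actin": delta_stat(grp.get("actin_standardized")),
                "delta_Ncadherin": delta_stat(grp.get("Ncadherin_standardized")),
                "mean_orientation": float(np.nanmean(
                    grp["orientation"].to_numpy(dtype=float)))
                if "orientation" in grp else np.nan,
            })
        out.junction_stats = pd.DataFrame(rows)
    return out


def quadrant_fractions(x, y) -> dict[str, float]:
    """Percentage of paired points in each sign quadrant of the (x, y) plane.

    Zero values count as non-negative.  Keys are ``x<0,y<0``, ``x<0,y>=0``,
    ``x>=0,y<0``, ``x>=0,y>=0``; values sum to 100 within rounding.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) == 0:
        raise ValueError("no paired points")
    n = len(x)
    return {
        "x<0,y<0": 100.0 * np.sum((x < 0) & (y < 0)) / n,
        "x<0,y>=0": 100.0 * np.sum((x < 0) & (y >= 0)) / n,
        "x>=0,y<0": 100.0 * np.sum((x >= 0) & (y < 0)) / n,
        "x>=0,y>=0": 100.0 * np.sum((x >= 0) & (y >= 0)) / n,
    }


def _runs(present: np.ndarray):
    """Yield (start, length) of maximal runs of True."""
    i, n = 0, len(present)
    while i < n:
        if present[i]:
            j = i
            while j < n and present[j]:
                j += 1
            yield i, j - i
            i = j
        else:
            i += 1


def detect_t1(
    adjacency: list[AdjacencyFrame],
    k_stable: int = 5,
    pair_window: int = 3,
) -> tuple[list[T1Event], dict]:
    """Detect stable T1 neighbor exchanges from per-frame adjacency.

    A loss of adjacency (a, b) persisting >= ``k_stable`` frames is paired
    with a gain (c, d) starting within ±``pair_window`` frames, where c and d
    are common neighbors of a and b around the event and the gain also
    persists >= ``k_stable`` frames.  Returns the event list and per-cell
    stable-exchange counts (each event increments all four cells).
    """
    frames = sorted(adjacency, key=lambda f: f.minute)
    minutes = [f.minute for f in frames]
    n = len(frames)
    all_pairs = set()
    for f in frames:
        all_pairs.update(f.pairs)
    present = {p: np.array([p in f.pairs for f in frames]) for p in all_pairs}

    def _stable_before(runs_map, start):
        """The run ending just before ``start`` is stable: it reaches the
        movie start or lasts >= k_stable frames (flicker echoes do neither)."""
        for s, length in runs_map:
            if s + length == start:
                return s == 0 or length >= k_stable
        return False

    losses = []  # (frame_index_of_first_absence, pair)
    gains = []   # (frame_index_of_first_presence, pair)
    for pair, pres in present.items():
        absent = ~pres
        pres_runs = list(_runs(pres))
        abs_runs = list(_runs(absent))
        for start, length in abs_runs:
            if start > 0 and length >= k_stable and _stable_before(pres_runs, start):
                losses.append((start, pair))
        for start, length in pres_runs:
            if start > 0 and length >= k_stable and _stable_before(abs_runs, start):
                gains.append((start, pair))

    events: list[T1Event] = []
    counts: dict = {}
    used_gains = set()
    for loss_idx, lost in sorted(losses):
        a, b = tuple(lost)
        # candidate gains ordered by frame proximity to the loss
        cands = sorted(
            (abs(g_idx - loss_idx), g_idx, gained)
            for g_idx, gained in gains
            if gained not in used_gains
            and abs(g_idx - loss_idx) <= pair_window
            and not (set(gained) & {a, b})
        )
        chosen = None
        for _, g_idx, gained in cands:
            c, d = tuple(gained)
            # c and d must be common neighbors of a and b just before the
            # exchange (the four cells meet around the collapsing edge)
            ref = frames[max(min(loss_idx, g_idx) - 1, 0)]
            na_, nb_ = ref.neighbors_of(a), ref.neighbors_of(b)
            if {c, d} <= na_ and {c, d} <= nb_:
                chosen = (g_idx, (c, d))
                break
        if chosen is None:
            continue
        g_idx, (c, d) = chosen
        used_gains.add(frozenset((c, d)))
        events.append(T1Event(
            losing_pair=(a, b),
            gaining_pair=(c, d),
            loss_frame=minutes[loss_idx],
            gain_frame=minutes[g_idx],
            stable=True,
        ))
        for cell in (a, b, c, d):
            counts[cell] = counts.get(cell, 0) + 1
    return events, counts
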
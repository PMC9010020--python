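"""Mosaic genotype calling and interface classification.

F0 CRISPR mosaics carry a membrane-BFP lineage tracer co-injected with
Cas9 + sgRNA, so crispant cells are bright in BFP and control cells dim.
Genotype is a property of a cell lineage, so each track gets one call based
on its track-mean medial BFP score: crispant iff score >= threshold.  The
threshold is a per-embryo manual override when configured, otherwise an
automatic bimodal split (between-class-variance maximization, i.e. Otsu, on
the log-intensity histogram).  Manual per-track overrides are applied last.

Junctions are classified from their flanking cells: control/control ->
control, crispant/crispant -> crispant, mixed -> at mosaic interface.  Cells
that ever touch the opposite genotype are interface-flagged and excluded
from quantitative comparisons downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from apicaltrack.tables_io import CONTROL, CRISPANT, INTERFACE, EmbryoConfig

__all__ = [
    "AdjacencyFrame",
    "call_genotype",
    "neighbor_counts",
    "flag_interface",
    "classify_junction",
    "annotate_dataset",
]

log = logging.getLogger(__name__)

# minimum Ashman-style separation |mu1 - mu0| / sqrt((s0² + s1²)/2) of the
# two Otsu classes for the score distribution to count as bimodal; an Otsu
# split of a single Gaussian yields ~2.7, a 5-s.d. two-mode mixture >= 5
_MIN_SEPARATION = 3.5
_MIN_CLASS_WEIGHT = 0.02


@dataclass(frozen=True)
class AdjacencyFrame:
    """Cell-cell contacts at one frame: unordered id pairs sharing a junction."""

    minute: int
    pairs: frozenset = field(default_factory=frozenset)

    def neighbors_of(self, cell) -> set:
        out = set()
        for p in self.pairs:
            if cell in p:
                (other,) = set(p) - {cell}
                out.add(other)
        return out


def _auto_threshold(scores: np.ndarray) -> tuple[float | None, str]:
    """Otsu threshold on the log10-score histogram (256 bins).

    Returns ``(None, reason)`` when the split does not look bimodal: the
    separation check is Ashman-style D on the linear-intensity classes,
    which is ~2.7 for an Otsu split of a single Gaussian and far larger for
    genuinely two-mode tracer distributions.
    """
    logs = np.log10(np.maximum(scores, 1e-12))
    if np.ptp(logs) == 0:
        return None, "all scores identical"
    t = float(10 ** threshold_otsu(logs, nbins=256))
    lo, hi = scores[scores < t], scores[scores >= t]
    if len(lo) < 1 or len(hi) < 1:
        return None, "one-sided split"
    w_lo = len(lo) / len(scores)
    if min(w_lo, 1 - w_lo) < _MIN_CLASS_WEIGHT:
        return None, "degenerate class weights"
    sep_sd = np.sqrt((lo.var() + hi.var()) / 2.0)
    if sep_sd == 0 or (hi.mean() - lo.mean()) / sep_sd < _MIN_SEPARATION:
        return None, "modes not separated"
    return t, "otsu(log10, 256 bins)"


def call_genotype(
    cells: pd.DataFrame,
    config: EmbryoConfig,
    score_column: str = "medial_memBFP",
) -> dict:
    """Call control vs crispant per cell track from membrane-BFP.

    Score = track-mean of ``score_column``.  Threshold precedence: config
    override > automatic bimodal split; if the score distribution is
    unimodal and no override is configured, every cell falls back to control
    with a warning.  ``config.genotype_overrides`` wins regardless of score.
    Returns ``{track_id: label}``.
    """
    sel = cells[cells["movie"] == config.movie] if "movie" in cells.columns else cells
    scores = sel.groupby("track_id_cells", sort=False)[score_column].mean()
    if config.bfp_threshold is not None:
        threshold, method = float(config.bfp_threshold), "config override"
    else:
        threshold, method = _auto_threshold(scores.to_numpy(dtype=float))
        if threshold is None:
            warnings.warn(
                f"movie {config.movie}: BFP score distribution looks unimodal "
                f"({method}); falling back to all-control calls"
            )
            labels = {tid: CONTROL for tid in scores.index}
            labels.update(config.genotype_overrides)
            return labels
    log.info("call_genotype: movie %s threshold %.6g (%s)",
             config.movie, threshold, method)
    labels = {
        tid: (CRISPANT if s >= threshold else CONTROL)
        for tid, s in scores.items()
    }
    labels.update(config.genotype_overrides)
    return labels


def neighbor_counts(adjacency: list[AdjacencyFrame], labels: dict) -> pd.DataFrame:
    """Per cell per frame counts of control and crispant neighbors.

    Raises ``KeyError`` naming the first unlabeled neighbor encountered.
    The two counts partition each cell's neighbor set.
    """
    rows = []
    for frame in adjacency:
        cells = set()
        for p in frame.pairs:
            cells.update(p)
        for cell in sorted(cells):
            n_ctrl = n_crisp = 0
            for nb in frame.neighbors_of(cell):
                if nb not in labels:
                    raise KeyError(f"cell {nb!r} has no genotype label")
                if labels[nb] == CRISPANT:
                    n_crisp += 1
                else:
                    n_ctrl += 1
            rows.append((frame.minute, cell, n_ctrl, n_crisp))
    return pd.DataFrame(
        rows, columns=["minute", "track_id_cells",
                       "control_neighbors", "crispant_neighbors"]
    )


def flag_interface(cell_label: str, counts: pd.DataFrame) -> bool:
    """True iff the cell ever had an opposite-genotype neighbor.

    ``counts`` holds that cell's per-frame control/crispant neighbor counts.
    """
    col = "control_neighbors" if cell_label == CRISPANT else "crispant_neighbors"
    return bool((counts[col] > 0).any())


def classify_junction(label_a: str, label_b: str) -> str:
    """Junction CRISPR status from its two flanking cell genotypes."""
    for lab in (label_a, label_b):
        if lab not in (CONTROL, CRISPANT):
            raise ValueError(f"unknown genotype label {lab!r}")
    if label_a == label_b:
        return label_a
    return INTERFACE


def annotate_dataset(
    cells: pd.DataFrame,
    adjacency: dict[str, list[AdjacencyFrame]],
    configs: dict[str, EmbryoConfig],
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Call genotypes, attach neighbor counts, and flag interface cells.

    ``adjacency`` maps movie -> per-frame adjacency.  Returns the annotated
    cell table (CRISPR, control_neighbors, crispant_neighbors filled), the
    per-(movie, track) label map, and a per-track interface-flag table.
    """
    cells = cells.copy()
    all_labels: dict = {}
    flag_rows = []
    for movie, cfg in configs.items():
        labels = call_genotype(cells, cfg)
        all_labels[movie] = labels
        sel = cells["movie"] == movie
        cells.loc[sel, "CRISPR"] = cells.loc[sel, "track_id_cells"].map(labels)
        counts = neighbor_counts(adjacency[movie], labels)
        merged = cells.loc[sel, ["track_id_cells", "minute"]].merge(
            counts, on=["track_id_cells", "minute"], how="left")
        cells.loc[sel, "control_neighbors"] = (
            merged["control_neighbors"].fillna(0).to_numpy(dtype=np.int64))
        cells.loc[sel, "crispant_neighbors"] = (
            merged["crispant_neighbors"].fillna(0).to_numpy(dtype=np.int64))
        for tid, grp in counts.groupby("track_id_cells", sort=False):
            if tid in labels:
                flag_rows.append(
                    (movie, tid, flag_interface(labels[tid], grp)))
    flags = pd.DataFrame(
        flag_rows, columns=["movie", "track_id_cells", "at_mosaic_interface"])
    return cells, all_labels, flags
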
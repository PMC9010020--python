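"""Per-cell medial/junctional domain intensities from label masks.

A :class:`LabelFrame` holds a segmented frame: an integer label image where 0
marks the 1-pixel boundary skeleton (and background) and k >= 1 marks cell k,
plus named channel images of the same shape.

Domain definitions:

* medial domain — the cell region eroded by one pixel (3×3 structuring
  element), i.e. the free apical surface inside the junctional belt;
* junctional domain — the skeleton pixels 8-adjacent to the cell region.

Domain intensity is the mean pixel value over the domain (total fluorescence
divided by area).  Pairwise junction pixel sets exclude vertex pixels
(skeleton pixels touching >= 3 cells) to avoid double counting; the per-cell
junctional domain keeps them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LabelFrame",
    "CellMeasurement",
    "split_domains",
    "mean_intensity",
    "measure_cell",
    "junction_pixels_and_z",
    "vertex_pixels",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class LabelFrame:
    """One segmented frame: label image plus channel images.

    ``labels`` uses 0 for the boundary skeleton/background and k >= 1 for
    cell k.  ``z_index_map`` optionally records which z-slice a
    maximum-intensity projection sampled at each pixel.
    """

    labels: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    z_index_map: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        for name, ch in self.channels.items():
            if np.asarray(ch).shape != self.labels.shape:
                raise ValueError(f"channel {name!r} shape mismatch")

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellMeasurement:
    """Measured geometry and per-domain channel means for one cell."""

    cell: int
    apical_area_pixels: int
    medial_means: dict[str, float]
    junctional_means: dict[str, float]
    degenerate: bool = False


def split_domains(frame: LabelFrame, cell: int):
    """Split a cell into its medial and junctional pixel masks.

    Returns ``(medial_mask, junctional_mask, degenerate)``.  The medial mask
    is the one-pixel erosion of the cell region; cells too small to survive
    erosion are flagged degenerate (empty medial mask).  The junctional mask
    is every skeleton pixel 8-adjacent to the region; the two are disjoint by
    construction.
    """
    region = frame.labels == cell
    if not region.any():
        raise ValueError(f"cell {cell} not present in frame")
    medial = ndimage.binary_erosion(region, structure=_SQUARE3)
    junctional = ndimage.binary_dilation(region, structure=_SQUARE3) & (frame.labels == 0)
    return medial, junctional, not medial.any()


def mean_intensity(mask: np.ndarray, channel: np.ndarray) -> float:
    """Mean of ``channel`` over ``mask`` pixels; NaN for an empty mask."""
    if not mask.any():
        return float("nan")
    return float(np.asarray(channel, dtype=float)[mask].mean())


def measure_cell(frame: LabelFrame, cell: int) -> CellMeasurement:
    """Apical area (medial pixel count) and per-domain channel means."""
    medial, junctional, degenerate = split_domains(frame, cell)
    med = {name: mean_intensity(medial, ch) for name, ch in frame.channels.items()}
    junc = {name: mean_intensity(junctional, ch) for name, ch in frame.channels.items()}
    return CellMeasurement(
        cell=int(cell),
        apical_area_pixels=int(medial.sum()),
        medial_means=med,
        junctional_means=junc,
        degenerate=degenerate,
    )


def vertex_pixels(frame: LabelFrame) -> np.ndarray:
    """Boolean mask of skeleton pixels 8-adjacent to >= 3 distinct cells."""
    labels = frame.labels
    skel = labels == 0
    count = np.zeros(labels.shape, dtype=np.int16)
    for cell in frame.cell_ids():
        near = ndimage.binary_dilation(labels == cell, structure=_SQUARE3)
        count[near] += 1
    return skel & (count >= 3)


def junction_pixels_and_z(
    frame: LabelFrame,
    cell_a: int,
    cell_b: int,
    z_stack: np.ndarray | None = None,
    z_step_micron: float = 1.0,
):
    """Pixels of the junction shared by two cells, channel means, and Δz.

    The junction pixel set is the skeleton pixels 8-adjacent to both regions,
    excluding vertex pixels (adjacent to >= 3 cells).  When a ``z_stack``
    (z, y, x) is supplied, each vertex's sampled depth is the argmax along z
    (ties resolve to the smallest z) and ``delta_z_micron`` is the absolute
    depth difference between the two junction endpoints times the z-step;
    with more than two vertex pixels the most distant pair is taken as the
    endpoints.
    """
    near_a = ndimage.binary_dilation(frame.labels == cell_a, structure=_SQUARE3)
    near_b = ndimage.binary_dilation(frame.labels == cell_b, structure=_SQUARE3)
    if not (frame.labels == cell_a).any() or not (frame.labels == cell_b).any():
        raise ValueError("both cells must be present in the frame")
    skel = frame.labels == 0
    shared = skel & near_a & near_b
    if not shared.any():
        raise ValueError(f"cells {cell_a} and {cell_b} are not adjacent")
    verts = vertex_pixels(frame)
    pix = shared & ~verts
    means = {name: mean_intensity(pix, ch) for name, ch in frame.channels.items()}

    delta_z = None
    if z_stack is not None:
        vmask = shared & verts
        coords = np.argwhere(vmask)
        if len(coords) >= 2:
            if len(coords) > 2:
                d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
                i, j = np.unravel_index(np.argmax(d2), d2.shape)
                coords = coords[[i, j]]
            zs = [int(np.argmax(z_stack[:, y, x])) for y, x in coords]
            delta_z = abs(zs[0] - zs[1]) * z_step_micron
        else:
            delta_z = 0.0
    return pix, means, delta_z
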
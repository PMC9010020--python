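"""Polygon metrics, z-corrected junction length, and axis-referenced
orientation.

Conventions: image coordinates with x rightward and y downward; angles in
degrees.  The embryonic mediolateral (ML) axis is at 0° and the
anteroposterior (AP) axis at 90°; a per-embryo ``ap_axis_angle_deg`` maps the
image frame onto the embryonic axes.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "polygon_area",
    "polygon_centroid",
    "corrected_length",
    "orientation",
    "classify_orientation",
]


def polygon_area(vertices) -> float:
    """Absolute shoelace area of a simple polygon, in px².

    Raises ``ValueError`` for fewer than 3 vertices or a self-intersecting
    ring.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValueError("polygon_area needs >= 3 (x, y) vertices")
    if not Polygon(v).is_valid:
        raise ValueError("self-intersecting polygon")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def polygon_centroid(vertices) -> tuple[float, float]:
    """Area centroid of a simple polygon (px)."""
    c = Polygon(np.asarray(vertices, dtype=float)).centroid
    return (c.x, c.y)


def corrected_length(length_micron: float, delta_z_micron: float) -> float:
    """Restore 3D junction length from its 2D projection.

    A junction whose two vertices were sampled at different depths appears
    foreshortened in a maximum-intensity projection; the true length is the
    Euclidean hypotenuse of the projected length and the vertex z-offset.
    """
    if length_micron < 0 or delta_z_micron < 0:
        raise ValueError("lengths must be non-negative")
    return math.hypot(length_micron, delta_z_micron)


def orientation(p1, p2, ap_axis_angle_deg: float = 90.0) -> float:
    """Angle of the segment p1-p2 relative to the embryonic ML axis.

    Returns degrees in [0, 90]: 0 = aligned with the ML axis, 90 = aligned
    with the AP axis.  Invariant to endpoint order and segment sign.
    """
    (x1, y1), (x2, y2) = p1, p2
    dx, dy = x2 - x1, y2 - y1
    if dx == 0 and dy == 0:
        raise ValueError("zero-length segment has no orientation")
    theta = math.degrees(math.atan2(dy, dx))
    ml_angle = ap_axis_angle_deg - 90.0
    # fold the axial (mod-180) angle difference into [0, 90]
    rel = (theta - ml_angle) % 180.0
    return min(rel, 180.0 - rel)


def classify_orientation(mean_orientation: float) -> str:
    """Classify a mean junction orientation as ``AP`` (< 45°) or ``ML``.

    An AP junction joins an anterior neighbor to a posterior one (its chord
    runs close to the ML axis); the 45° boundary itself classifies as ML.
    """
    if not 0.0 <= mean_orientation <= 90.0:
        raise ValueError("orientation must lie in [0, 90]")
    return "AP" if mean_orientation < 45.0 else "ML"
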
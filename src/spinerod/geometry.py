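"""Shared centerline-geometry helpers.

Coordinate convention (fixed package-wide): Z is cranio-caudal (up), Y is
anterior(+)/posterior(-), X is left/right.  The sagittal plane is Y-Z, the
frontal plane X-Z and the axial (top-view) plane X-Y.  Curves are stored as
``(n, 3)`` arrays ordered cranially to caudally (T1 first, L5 last).
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["curve_height", "isotropic_normalize", "arc_length", "polyline_length"]


def curve_height(coords: np.ndarray) -> float:
    """Vertical (Z) extent of a centerline."""
    coords = np.asarray(coords, dtype=float)
    return float(coords[:, 2].max() - coords[:, 2].min())


def isotropic_normalize(coords: np.ndarray) -> np.ndarray:
    """Similarity-normalize a centerline to unit height.

    One uniform scale factor is applied to X, Y and Z so that the vertical
    extent becomes exactly 1, then the curve is translated so its bottom
    (caudal, last) landmark sits at the origin.  Ratios of inter-landmark
    distances are preserved exactly.
    """
    coords = np.asarray(coords, dtype=float)
    h = curve_height(coords)
    if h <= 0.0:
        raise DegenerateGeometryError("cannot normalize a curve with zero height")
    out = coords / h
    return out - out[-1]


def arc_length(coords: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    coords = np.asarray(coords, dtype=float)
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_length(coords: np.ndarray) -> float:
    """Total length of a polyline."""
    return float(arc_length(coords)[-1])
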
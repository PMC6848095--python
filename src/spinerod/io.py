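"""Landmark CSV and mesh export.

The exchange format is a landmark CSV with header ``level,x,y,z``, levels
ordered T1..L5 cranially to caudally, floating point written with 17
significant digits so a read/write round trip is lossless to well below
1e-12.  Deformed/initial centerlines can additionally be exported as legacy
ASCII VTK polylines for visualization.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .profiles import SagittalProfile

__all__ = ["write_landmarks_csv", "read_landmarks_csv", "write_vtk_polyline"]


def write_landmarks_csv(path: str | Path, profile: SagittalProfile | np.ndarray,
                        levels: list[str] | None = None) -> None:
    """Write a centerline to a landmark CSV (header ``level,x,y,z``)."""
    if isinstance(profile, SagittalProfile):
        coords, levels = profile.coords, list(profile.levels)
    else:
        coords = np.asarray(profile, dtype=float)
        if levels is None:
            levels = [f"V{i + 1}" for i in range(coords.shape[0])]
    df = pd.DataFrame({"level": levels, "x": coords[:, 0],
                       "y": coords[:, 1], "z": coords[:, 2]})
    df.to_csv(path, index=False, float_format="%.17g")


def read_landmarks_csv(path: str | Path,
                       group_tag: str = "Custom") -> SagittalProfile:
    """Read a landmark CSV back into a profile (no re-normalization)."""
    df = pd.read_csv(path)
    required = {"level", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"landmark CSV must have columns {sorted(required)}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return SagittalProfile(levels=tuple(df["level"].astype(str)),
                           coords=coords, group_tag=group_tag)


def write_vtk_polyline(path: str | Path, *curves: np.ndarray) -> None:
    """Write one or more 3D polylines to a legacy ASCII VTK file."""
    curves = tuple(np.asarray(c, dtype=float) for c in curves)
    n_total = sum(c.shape[0] for c in curves)
    lines = ["# vtk DataFile Version 3.0", "spinerod centerlines", "ASCII",
             "DATASET POLYDATA", f"POINTS {n_total} double"]
    for c in curves:
        for p in c:
            lines.append(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}")
    size = sum(c.shape[0] + 1 for c in curves)
    lines.append(f"LINES {len(curves)} {size}")
    offset = 0
    for c in curves:
        ids = " ".join(str(offset + i) for i in range(c.shape[0]))
        lines.append(f"{c.shape[0]} {ids}")
        offset += c.shape[0]
    Path(path).write_text("\n".join(lines) + "\n")
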
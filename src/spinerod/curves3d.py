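"""Synthetic 3D scoliotic centerline curves.

These curves emulate the two axial-projection archetypes of right-thoracic
scoliotic spines: a *loop* (V-shaped top view, single-signed projected
curvature) and a *lemniscate* (S-shaped top view, one self-crossing,
figure-eight).  They serve as fixtures for the axial-projection classifier
and for clustering experiments; they are not solver inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .geometry import isotropic_normalize

__all__ = ["generate_scoliotic_curve_3d", "CurveFamily", "generate_curve_cohort",
           "FIVE_TYPE_FAMILIES"]


def generate_scoliotic_curve_3d(archetype: str, amplitude: float, seed: int = 0,
                                n_points: int = 17, noise_sd: float = 0.0,
                                phase_deg: float = 0.0) -> np.ndarray:
    """Unit-height 3D curve whose axial projection is a loop or a lemniscate.

    The loop projection follows a circular arc (sweep angle pi); the
    lemniscate follows a 1:2 Lissajous figure-eight with one self-crossing.
    ``amplitude`` scales the lateral extent relative to the unit height;
    ``amplitude=0`` degenerates to a straight vertical line.  ``phase_deg``
    rotates the projection about Z (used to build distinguishable cluster
    families).  Noise jitters all coordinates per landmark.
    """
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be non-negative")
    if n_points < 5:
        raise InvalidParameterError("n_points must be at least 5")
    s = np.linspace(0.0, 1.0, n_points)
    if archetype == "loop":
        theta = np.pi * s
        x = amplitude * np.sin(theta)
        y = amplitude * (1.0 - np.cos(theta)) / 2.0
    elif archetype == "lemniscate":
        theta = 2.0 * np.pi * s
        x = amplitude * np.sin(theta)
        y = 0.6 * amplitude * np.sin(2.0 * theta)
    else:
        raise InvalidParameterError(f"unknown archetype {archetype!r}")
    c, sn = np.cos(np.radians(phase_deg)), np.sin(np.radians(phase_deg))
    xr, yr = c * x - sn * y, sn * x + c * y
    coords = np.column_stack([xr, yr, 1.0 - s])  # cranial (top) first
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
        coords = isotropic_normalize(coords)
    return coords


@dataclass(frozen=True)
class CurveFamily:
    """One synthetic cluster family for classification experiments."""

    name: str
    archetype: str
    amplitude: float
    phase_deg: float = 0.0


#: Stand-ins for the five right-thoracic subtypes: Types 2 and 4 loop-shaped
#: (Group I), Types 1, 3 and 5 lemniscate-shaped (Group II), separated in
#: amplitude and axial orientation.
FIVE_TYPE_FAMILIES = (
    CurveFamily("Type1", "lemniscate", 0.08, 0.0),
    CurveFamily("Type2", "loop", 0.10, 0.0),
    CurveFamily("Type3", "lemniscate", 0.05, 60.0),
    CurveFamily("Type4", "loop", 0.06, 120.0),
    CurveFamily("Type5", "lemniscate", 0.11, 30.0),
)


def generate_curve_cohort(families: tuple[CurveFamily, ...], n_per_family: int,
                          noise_sd: float, seed: int,
                          n_points: int = 17) -> tuple[np.ndarray, np.ndarray]:
    """Generate a labelled cohort of noisy 3D curves, one family per label.

    Returns ``(curves, labels)`` with curves of shape
    ``(n_families * n_per_family, n_points, 3)`` and integer labels.
    """
    rng = np.random.default_rng(seed)
    curves, labels = [], []
    for idx, fam in enumerate(families):
        for _ in range(n_per_family):
            sub = int(rng.integers(0, 2 ** 31 - 1))
            curves.append(generate_scoliotic_curve_3d(
                fam.archetype, fam.amplitude, seed=sub, n_points=n_points,
                noise_sd=noise_sd, phase_deg=fam.phase_deg))
            labels.append(idx)
    return np.asarray(curves), np.asarray(labels)
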
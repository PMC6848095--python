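"""Synthetic sagittal spine profiles.

A sagittal profile is a planar S-shaped curve through the 17 vertebral
centroids T1..L5, normalized isotropically to unit height.  Profiles are
built from a two-segment curvature law: a caudal lordotic segment of
positive sagittal curvature and a cranial kyphotic segment of negative
curvature, joined at a single inflection point.  The curvature within each
segment follows a half-sine bump, which vanishes smoothly at the joint and
gives a C2 curve; the tangent at L5 is vertical (zero sacral slope).

Vertebral levels sit at equal vertical spacing before normalization; the
curve is the graph Y(Z) in the sagittal plane, so it can never
self-intersect, but anatomically implausible amplitudes (sagittal slope
exceeding ~60 degrees from vertical) are rejected as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateGeometryError, InvalidParameterError
from .geometry import curve_height, isotropic_normalize

__all__ = [
    "LEVELS_17",
    "ProfileParams",
    "SagittalProfile",
    "generate_sagittal_profile",
    "interpolate_profiles",
]

LEVELS_17 = tuple(f"T{i}" for i in range(1, 13)) + tuple(f"L{i}" for i in range(1, 6))

#: Largest allowed sagittal slope |dY/dZ| for a generated profile.
_MAX_SLOPE = 1.75


def _level_labels(n: int) -> tuple[str, ...]:
    return LEVELS_17 if n == 17 else tuple(f"V{i}" for i in range(1, n + 1))


@dataclass(frozen=True)
class ProfileParams:
    """Parameters of a two-segment synthetic sagittal profile.

    ``kyphotic_len`` counts the vertebrae in the cranial (kyphotic, concave)
    segment adjacent to T1; ``lordotic_len`` those in the caudal (lordotic)
    segment adjacent to L5.  The inflection point lies midway between the
    last kyphotic and the first lordotic vertebra.  Amplitudes are the peak
    sagittal offsets of each segment from its own chord, in units of the
    (unit) spine height.
    """

    kyphotic_len: int
    lordotic_len: int
    kyphosis_amplitude: float = 0.07
    lordosis_amplitude: float = 0.06
    n_levels: int = 17
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 5:
            raise InvalidParameterError("n_levels must be at least 5")
        if self.kyphotic_len + self.lordotic_len != self.n_levels:
            raise InvalidParameterError(
                "kyphotic_len + lordotic_len must equal n_levels "
                f"({self.kyphotic_len}+{self.lordotic_len} != {self.n_levels})"
            )
        if min(self.kyphotic_len, self.lordotic_len) < 1:
            raise InvalidParameterError("segment lengths must be positive")
        if self.kyphosis_amplitude < 0 or self.lordosis_amplitude < 0:
            raise InvalidParameterError("amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")

    @property
    def inflection_level(self) -> int:
        """Index (0-based from T1) of the last kyphotic vertebra."""
        return self.kyphotic_len - 1


@dataclass(frozen=True)
class SagittalProfile:
    """Ordered vertebral centroids of a unit-height spinal centerline.

    ``coords`` has one row per level, ordered T1 (cranial) to L5 (caudal),
    columns (X, Y, Z).  Generated sagittal profiles are planar: X is
    identically zero.
    """

    levels: tuple[str, ...]
    coords: np.ndarray
    group_tag: str = "Custom"
    params: ProfileParams | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidParameterError("coords must be an (n, 3) array")
        if len(self.levels) != coords.shape[0]:
            raise InvalidParameterError("levels and coords length mismatch")
        object.__setattr__(self, "coords", coords)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def height(self) -> float:
        return curve_height(self.coords)

    def is_planar(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.coords[:, 0]) <= tol))


def _two_arc_sagittal_y(z: np.ndarray, z_infl: float, c_kyph: float,
                        c_lord: float) -> np.ndarray:
    """Closed-form double integral of the two half-sine curvature bumps.

    Curvature law (with z measured upward from L5 at z=0 to T1 at z=1):
    kappa = +c_lord * sin(pi z / z_infl)            on the lordotic zone,
    kappa = -c_kyph * sin(pi (z-z_infl)/(1-z_infl)) on the kyphotic zone,
    integrated with Y(0) = Y'(0) = 0 (vertical sacral tangent).
    """
    L1, L2 = z_infl, 1.0 - z_infl
    y = np.empty_like(z)
    lo = z <= z_infl
    zl = z[lo]
    y[lo] = c_lord * L1 / np.pi * (zl - L1 / np.pi * np.sin(np.pi * zl / L1))
    u = z[~lo] - z_infl
    y_i = c_lord * L1 ** 2 / np.pi          # Y at the inflection
    yp_i = 2.0 * c_lord * L1 / np.pi        # Y' at the inflection
    y[~lo] = (y_i + yp_i * u
              - c_kyph * L2 / np.pi * (u - L2 / np.pi * np.sin(np.pi * u / L2)))
    return y


def _chord_deviation(z: np.ndarray, y: np.ndarray) -> float:
    """Peak |deviation| of the graph (z, y) from its end-to-end chord."""
    chord = y[0] + (y[-1] - y[0]) * (z - z[0]) / (z[-1] - z[0])
    return float(np.max(np.abs(y - chord)))


def generate_sagittal_profile(params: ProfileParams,
                              group_tag: str = "Custom") -> SagittalProfile:
    """Generate a planar S-shaped sagittal profile from segment parameters.

    The two curvature-bump amplitudes are rescaled so that the peak offset of
    each segment from its own chord equals the requested amplitude exactly
    (the deviation of either segment from its chord is linear in that
    segment's curvature amplitude alone).  With ``noise_sd=0`` the output is
    deterministic; noise jitters Y and Z per landmark (the profile stays in
    the sagittal plane), after which the curve is re-normalized to unit
    height with L5 at the origin.
    """
    n = params.n_levels
    # Vertebral heights before normalization, T1 at z=1 down to L5 at z=0.
    z = 1.0 - np.arange(n) / (n - 1)
    z_infl = 1.0 - (params.kyphotic_len - 0.5) / (n - 1)

    z_dense = np.linspace(0.0, 1.0, 801)
    y_unit_l = _two_arc_sagittal_y(z_dense, z_infl, 0.0, 1.0)
    y_unit_k = _two_arc_sagittal_y(z_dense, z_infl, 1.0, 0.0)
    lo = z_dense <= z_infl
    d_l = _chord_deviation(z_dense[lo], y_unit_l[lo])
    d_k = _chord_deviation(z_dense[~lo], y_unit_k[~lo])
    c_lord = params.lordosis_amplitude / d_l if d_l > 0 else 0.0
    c_kyph = params.kyphosis_amplitude / d_k if d_k > 0 else 0.0

    y_raw = _two_arc_sagittal_y(z, z_infl, c_kyph, c_lord)
    # Shear so T1 sits plumb above L5 (sagittally balanced spine).  Shear
    # leaves Y'' and each segment's chord deviation unchanged; the sacral
    # slope becomes the emergent angle that balance requires, which turns
    # the profile into a true two-lobed S around the plumb line (anterior
    # lumbar lobe, posterior thoracic lobe).
    y = y_raw - z * y_raw[0]          # y_raw[0] is the T1 (z=1) offset

    y_dense = _two_arc_sagittal_y(z_dense, z_infl, c_kyph, c_lord)
    y_dense = y_dense - z_dense * y_dense[-1]
    slope = np.max(np.abs(np.gradient(y_dense, z_dense)))
    if slope > _MAX_SLOPE:
        raise DegenerateGeometryError(
            f"amplitudes give sagittal slope {slope:.2f} > {_MAX_SLOPE}; "
            "profile is anatomically degenerate")

    coords = np.column_stack([np.zeros(n), y, z])
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        coords[:, 1:] += rng.normal(0.0, params.noise_sd, size=(n, 2))
    coords = isotropic_normalize(coords)   # rows already T1 (z=1) down to L5 (z=0)
    return SagittalProfile(levels=_level_labels(n), coords=coords,
                           group_tag=group_tag, params=params)


def interpolate_profiles(a: SagittalProfile, b: SagittalProfile,
                         t: float) -> SagittalProfile:
    """Per-level convex combination of two profiles, re-normalized.

    ``t=0`` returns ``a`` (up to re-normalization), ``t=1`` returns ``b``.
    """
    if not 0.0 <= t <= 1.0:
        raise InvalidParameterError(f"interpolation weight t={t} outside [0, 1]")
    if a.n_levels != b.n_levels:
        raise InvalidParameterError("profiles must have equal level counts")
    coords = (1.0 - t) * a.coords + t * b.coords
    return SagittalProfile(levels=a.levels, coords=isotropic_normalize(coords),
                           group_tag="Interpolated")
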
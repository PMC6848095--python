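"""Quantitative 3D shape descriptors of spinal centerlines.

* ``global_torsion`` — arc-length-weighted mean of the discrete Frenet
  torsion, the standard scalar summary of a spinal curve's out-of-plane
  winding.  Planar curves score zero; a mirror image negates the sign
  (right-handed convention); the value scales as 1/s under uniform scaling.
* ``classify_axial_projection`` — line / loop / lemniscate topology of the
  top-view (X-Y) projection, from the sign structure of the projected
  curvature.
* ``axial_twist_count`` — the topological twist count (line 0, loop 1,
  lemniscate 2) of the axial projection, in the loop / twisted-loop sense
  of rod mechanics.
* ``count_twists`` — how many times the deformed centerline crosses its
  original sagittal plane (sign changes of the out-of-plane displacement).
* ``find_inflection`` — vertebral level where the sagittal curvature changes
  sign, splitting the spine into kyphotic and lordotic segments.
* ``displacement_ratio`` — signed mean lateral over mean sagittal
  displacement of a deformation field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (InputMismatchError, InsufficientDataError,
                     InvalidParameterError, UndefinedRatioError)
from .profiles import SagittalProfile

__all__ = [
    "ShapeMetrics", "InflectionResult", "global_torsion",
    "classify_axial_projection", "count_twists", "axial_twist_count",
    "find_inflection", "displacement_ratio",
]

#: Curvature floor below which local Frenet torsion is treated as undefined
#: (straight pieces contribute zero), per unit curve height.
KAPPA_MIN = 1e-6
#: Gate for the line / loop-lemniscate decision: RMS deviation of the axial
#: projection from its best-fit line, per unit curve height.
EPS_LINE = 1e-6
#: Dead band on signed quantities before sign-change counting, per unit
#: height, to suppress numerical zero-crossing chatter.
DEAD_BAND = 1e-8


@dataclass(frozen=True)
class InflectionResult:
    """Outcome of the sagittal inflection-point search."""

    has_inflection: bool
    inflection_level: int | None     # 0-based index of last kyphotic vertebra
    kyphotic_len: int
    lordotic_len: int


@dataclass(frozen=True)
class ShapeMetrics:
    """One row of shape descriptors for a solved rod model."""

    run_id: str
    group: str
    global_torsion: float
    axial_class: str
    twist_count: int          # topological (axial) twist count
    plane_crossings: int      # crossings of the original sagittal plane
    xy_ratio: float
    inflection_level: int | None
    kyphotic_len: int
    lordotic_len: int


def _smooth3(x: np.ndarray) -> np.ndarray:
    """Length-preserving 3-point moving average (ends averaged one-sidedly)."""
    if x.size < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


def _count_sign_changes(x: np.ndarray, dead_band: float) -> int:
    """Sign changes of a sequence after zeroing the dead band."""
    s = np.sign(np.where(np.abs(x) <= dead_band, 0.0, x))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def _height(coords: np.ndarray) -> float:
    h = float(coords[:, 2].max() - coords[:, 2].min())
    return h if h > 0 else 1.0


def writhe_per_length(curve: np.ndarray) -> float:
    """Writhe of an open polyline per unit length (Gauss double integral).

    Discrete pairwise solid-angle formula over non-adjacent segment pairs;
    provided as an alternative global-torsion strategy for sensitivity
    checks (writhe measures the same out-of-plane winding but integrates
    the chirality of the whole curve rather than local Frenet torsion).
    """
    p = np.asarray(curve, dtype=float)
    if p.shape[0] < 4:
        raise InsufficientDataError("writhe needs at least 4 points")
    e = np.diff(p, axis=0)
    n = e.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            r13 = p[j] - p[i]
            r14 = p[j + 1] - p[i]
            r23 = p[j] - p[i + 1]
            r24 = p[j + 1] - p[i + 1]
            n1 = np.cross(r13, r14)
            n2 = np.cross(r14, r24)
            n3 = np.cross(r24, r23)
            n4 = np.cross(r23, r13)
            norms = [np.linalg.norm(v) for v in (n1, n2, n3, n4)]
            if min(norms) < 1e-300:
                continue
            n1, n2, n3, n4 = (v / m for v, m in zip((n1, n2, n3, n4), norms))
            omega = (np.arcsin(np.clip(n1 @ n2, -1, 1))
                     + np.arcsin(np.clip(n2 @ n3, -1, 1))
                     + np.arcsin(np.clip(n3 @ n4, -1, 1))
                     + np.arcsin(np.clip(n4 @ n1, -1, 1)))
            sign = np.sign(np.cross(e[j], e[i]) @ r13)
            total += omega * sign / (4.0 * np.pi)
    length = float(np.sum(np.linalg.norm(e, axis=1)))
    if length == 0.0:
        return 0.0
    return 2.0 * total / length


def global_torsion(curve: np.ndarray, kappa_min: float | None = None,
                   weight: str = "curvature2", method: str = "frenet") -> float:
    """Weighted mean discrete Frenet torsion of a 3D polyline.

    Derivatives with respect to arc length are estimated by central finite
    differences; the local torsion is (r' x r'') . r''' / |r' x r''|^2.
    Points whose curvature falls below ``kappa_min`` (torsion undefined on
    straight pieces) contribute zero.  A fully collinear curve returns 0.

    ``weight`` selects the averaging strategy: ``"curvature2"`` (default)
    weights each arc element by its squared curvature, which damps the
    ill-conditioned near-straight regions of nearly planar spinal curves
    while leaving curves of constant curvature (the helix oracle) exact;
    ``"arc"`` is the plain arc-length-weighted mean.  ``method="writhe"``
    swaps in the writhe-per-length strategy for sensitivity checks.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 3:
        raise InsufficientDataError("curve must be an (n, 3) array")
    if curve.shape[0] < 4:
        raise InsufficientDataError("global torsion needs at least 4 points")
    if method == "writhe":
        return writhe_per_length(curve)
    if method != "frenet":
        raise InvalidParameterError(f"unknown torsion method {method!r}")
    if kappa_min is None:
        kappa_min = KAPPA_MIN / _height(curve)

    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return 0.0
    r1 = np.gradient(curve, s, axis=0)
    r2 = np.gradient(r1, s, axis=0)
    r3 = np.gradient(r2, s, axis=0)
    cr = np.cross(r1, r2)
    denom = np.einsum("ij,ij->i", cr, cr)
    kappa = np.sqrt(denom) / np.maximum(np.linalg.norm(r1, axis=1), 1e-300) ** 3
    num = np.einsum("ij,ij->i", cr, r3)
    # Torsion is ill-conditioned where the curve is locally straight; mask
    # both below the absolute floor and where curvature is a small fraction
    # of the curve's own peak curvature.
    floor = max(kappa_min, 1e-3 * float(kappa.max(initial=0.0)))
    tau = np.where(kappa > floor, num / np.maximum(denom, 1e-300), 0.0)

    # Interior points only: one-sided end differences are low order.
    interior = slice(2, curve.shape[0] - 2)
    w = np.gradient(s)[interior]
    if weight == "curvature2":
        w = w * kappa[interior] ** 2
    elif weight != "arc":
        raise InvalidParameterError(f"unknown torsion weight {weight!r}")
    t = tau[interior]
    if w.sum() == 0.0:
        return 0.0
    return float(np.sum(w * t) / np.sum(w))


def classify_axial_projection(curve: np.ndarray,
                              eps_line: float | None = None,
                              dead_band: float | None = None) -> str:
    """Classify the top-view projection of a 3D curve.

    Projects onto the X-Y plane.  If the RMS perpendicular deviation of the
    projected points from their best-fit (total least squares) line is below
    ``eps_line`` times the curve height, the projection is a *line*.
    Otherwise the smoothed projected path's signed curvature is examined:
    no sign change means *loop*, one or more means *lemniscate*.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape[0] < 5:
        raise InsufficientDataError("classification needs at least 5 points")
    h = _height(curve)
    if eps_line is None:
        eps_line = EPS_LINE
    pts = curve[:, :2]
    centered = pts - pts.mean(axis=0)
    # TLS line fit via the principal direction; residual = minor-axis spread.
    _, sv, _ = np.linalg.svd(centered, full_matrices=False)
    rms_resid = sv[-1] / np.sqrt(pts.shape[0])
    if rms_resid <= eps_line * h:
        return "line"

    scale = np.sqrt(np.mean(np.sum(centered ** 2, axis=1)))
    p = np.column_stack([_smooth3(pts[:, 0]), _smooth3(pts[:, 1])]) / scale
    e = np.diff(p, axis=0)
    cross = e[:-1, 0] * e[1:, 1] - e[:-1, 1] * e[1:, 0]
    band = (DEAD_BAND if dead_band is None else dead_band)
    changes = _count_sign_changes(cross, band)
    return "loop" if changes == 0 else "lemniscate"


def axial_twist_count(curve: np.ndarray,
                      eps_line: float | None = None,
                      dead_band: float | None = None) -> int:
    """Number of twists of a curve in the loop / twisted-loop sense.

    The axial (top-view) projection is scored by its lobe count: a straight
    projection has no twist (0), a single-signed-curvature arc — a loop —
    one twist (1), and each additional sign change of the projected
    curvature (a lemniscate has one, making a figure-eight) adds a further
    twist.  This is the topological twist count of rod mechanics, where a
    loop turns into a twisted loop (lemniscate) as torsional energy grows;
    it complements ``count_twists``, which counts crossings of the original
    sagittal plane.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape[0] < 5:
        raise InsufficientDataError("twist count needs at least 5 points")
    h = _height(curve)
    if eps_line is None:
        eps_line = EPS_LINE
    pts = curve[:, :2]
    centered = pts - pts.mean(axis=0)
    _, sv, _ = np.linalg.svd(centered, full_matrices=False)
    if sv[-1] / np.sqrt(pts.shape[0]) <= eps_line * h:
        return 0
    scale = np.sqrt(np.mean(np.sum(centered ** 2, axis=1)))
    p = np.column_stack([_smooth3(pts[:, 0]), _smooth3(pts[:, 1])]) / scale
    e = np.diff(p, axis=0)
    cross = e[:-1, 0] * e[1:, 1] - e[:-1, 1] * e[1:, 0]
    band = DEAD_BAND if dead_band is None else dead_band
    return 1 + _count_sign_changes(cross, band)


def count_twists(initial: np.ndarray, deformed: np.ndarray,
                 dead_band: float | None = None) -> int:
    """Number of crossings of the original sagittal plane by the deformed rod.

    Counts interior sign changes (after 3-point smoothing and a dead band)
    of the out-of-plane displacement component u_X along the curve: 0 means
    planar deformation, 1 one twist, 2 two twists.
    """
    initial = np.asarray(initial, dtype=float)
    deformed = np.asarray(deformed, dtype=float)
    if initial.shape != deformed.shape:
        raise InputMismatchError("initial and deformed curves differ in shape")
    ux = _smooth3(deformed[:, 0] - initial[:, 0])
    band = (DEAD_BAND * _height(initial)) if dead_band is None else dead_band
    return _count_sign_changes(ux, band)


def find_inflection(profile: SagittalProfile | np.ndarray,
                    dead_band: float | None = None) -> InflectionResult:
    """Locate the sagittal inflection point of a planar profile.

    Computes the discrete signed curvature at interior vertebral levels
    (cross product of consecutive sagittal-plane edge vectors).  The
    inflection is the level at which the sign changes, or the center of a
    contiguous near-zero transition zone between opposite signs.  The
    kyphotic segment is the one adjacent to T1.  Profiles with no sign
    change (C-shaped or straight) return ``has_inflection=False``.
    """
    coords = profile.coords if isinstance(profile, SagittalProfile) else np.asarray(profile, dtype=float)
    n = coords.shape[0]
    if n < 5:
        raise InsufficientDataError("inflection search needs at least 5 levels")
    yz = coords[:, 1:]                      # sagittal plane
    # Signed curvature evaluated locally at each interior level through a
    # cubic-spline fit in arc length; pointwise evaluation keeps a steep
    # short segment from bleeding across the inflection into its neighbor
    # (a 3-point estimate integrates over the straddling triple).
    seg = np.linalg.norm(np.diff(yz, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    spl = CubicSpline(s, yz, axis=0)
    d1 = spl(s[1:-1], 1)
    d2 = spl(s[1:-1], 2)
    cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    band = (DEAD_BAND * _height(coords)) if dead_band is None else dead_band
    sgn = np.sign(np.where(np.abs(cross) <= band, 0.0, cross))

    nz = np.nonzero(sgn)[0]
    if nz.size == 0 or len(set(sgn[nz])) < 2:
        return InflectionResult(False, None, 0, 0)
    # Walk the nonzero signs for the first transition; near-zero gaps between
    # opposite signs resolve to the central level of the gap.
    first_change = None
    for a, b in zip(nz[:-1], nz[1:]):
        if sgn[a] != sgn[b]:
            first_change = (a, b)
            break
    if first_change is None:
        return InflectionResult(False, None, 0, 0)
    a, b = first_change
    # cross index i corresponds to vertebral level i+1.
    level_a, level_b = a + 1, b + 1
    boundary = (level_a + level_b) // 2 if b - a > 1 else level_a
    kyph = boundary + 1                     # levels 0..boundary inclusive
    return InflectionResult(True, boundary, kyph, n - kyph)


def displacement_ratio(initial: np.ndarray, deformed: np.ndarray) -> float:
    """Signed mean X displacement over signed mean Y displacement."""
    initial = np.asarray(initial, dtype=float)
    deformed = np.asarray(deformed, dtype=float)
    if initial.shape != deformed.shape:
        raise InputMismatchError("initial and deformed curves differ in shape")
    u = deformed - initial
    mean_y = u[:, 1].mean()
    if mean_y == 0.0:
        raise UndefinedRatioError("mean Y displacement is zero; ratio undefined")
    return float(u[:, 0].mean() / mean_y)
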
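"""Batched rotation algebra for the corotational rod element.

All routines operate on arrays with arbitrary leading (batch) dimensions and
are written to remain holomorphic in their inputs, so that complex-step
differentiation of the element energy yields machine-precision gradients:
no absolute values, no ``arctan2``, and branch decisions taken on real
parts only.  Rotation logs are only ever taken of rotations well inside the
injectivity radius (local elastic rotations and half relative rotations of
adjacent nodes), where the principal branch is the correct one.
"""

from __future__ import annotations

import numpy as np

__all__ = ["exp_so3", "log_so3", "normalize", "cross", "mean_triad"]

_EYE = np.eye(3)


def cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product over the last axis (complex-safe)."""
    out = np.empty(np.broadcast(a, b).shape, dtype=np.result_type(a, b))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def normalize(v: np.ndarray) -> np.ndarray:
    """Unit vector along the last axis, using a holomorphic norm."""
    n = np.sqrt(np.sum(v * v, axis=-1, keepdims=True))
    return v / n


def _hat(w: np.ndarray) -> np.ndarray:
    """Skew matrix of a batch of 3-vectors."""
    shape = w.shape[:-1] + (3, 3)
    K = np.zeros(shape, dtype=w.dtype)
    K[..., 0, 1] = -w[..., 2]
    K[..., 0, 2] = w[..., 1]
    K[..., 1, 0] = w[..., 2]
    K[..., 1, 2] = -w[..., 0]
    K[..., 2, 0] = -w[..., 1]
    K[..., 2, 1] = w[..., 0]
    return K


def exp_so3(w: np.ndarray) -> np.ndarray:
    """Rodrigues exponential of rotation vectors (batched, holomorphic)."""
    t2 = np.sum(w * w, axis=-1)[..., None, None]
    t = np.sqrt(t2)
    small = np.real(t2) < 1e-12
    # sin(t)/t and (1-cos t)/t^2 with series fallbacks near zero.
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(small, 1.0 - t2 / 6.0 + t2 * t2 / 120.0,
                     np.sin(np.where(small, 1.0, t)) / np.where(small, 1.0, t))
        b = np.where(small, 0.5 - t2 / 24.0 + t2 * t2 / 720.0,
                     (1.0 - np.cos(np.where(small, 1.0, t))) / np.where(small, 1.0, t2))
    K = _hat(w)
    K2 = K @ K
    return _EYE + a * K + b * K2


def log_so3(R: np.ndarray) -> np.ndarray:
    """Rotation vector of rotations with angle < pi/2 (batched, holomorphic).

    Uses theta = arctan(sin/cos) on the skew part, valid on the branch the
    corotational formulation operates in (small local rotations).
    """
    w = 0.5 * np.stack([
        R[..., 2, 1] - R[..., 1, 2],
        R[..., 0, 2] - R[..., 2, 0],
        R[..., 1, 0] - R[..., 0, 1],
    ], axis=-1)                                   # sin(theta) * axis
    c = 0.5 * (np.trace(R, axis1=-2, axis2=-1) - 1.0)   # cos(theta)
    s2 = np.sum(w * w, axis=-1)
    small = np.real(s2) < 1e-12
    s = np.sqrt(np.where(small, 1.0, s2))
    with np.errstate(invalid="ignore", divide="ignore"):
        # f = theta/sin(theta); theta = arctan(tan(theta)) on the principal branch
        f = np.where(small, 1.0 + s2 / 6.0 + 7.0 * s2 * s2 / 360.0,
                     np.arctan(np.where(small, 1.0, s / c)) / np.where(small, 1.0, s))
    return w * f[..., None]


def mean_triad(A1: np.ndarray, A2: np.ndarray) -> np.ndarray:
    """Geodesic midpoint of two triads (rotation averaging)."""
    rel = np.swapaxes(A1, -1, -2) @ A2
    return A1 @ exp_so3(0.5 * log_so3(rel))
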
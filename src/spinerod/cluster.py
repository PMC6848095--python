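"""K-means classification of isotropically normalized 3D spinal centerlines.

Curves sharing a common 17-landmark parameterization are embedded as
concatenated (X, Y, Z) coordinate vectors (3 x n_levels dimensions) and
partitioned by k-means with the cluster count known a priori, mirroring the
patient-stratification stage of the scoliosis subtype analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .errors import InvalidParameterError
from .geometry import isotropic_normalize

__all__ = ["CurveCohort", "ClusteringResult", "cluster_curves", "label_agreement"]


@dataclass
class CurveCohort:
    """A stack of same-length 3D centerline curves, optionally labelled."""

    curves: np.ndarray                    # (m, n_points, 3)
    true_labels: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.curves, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise InvalidParameterError("curves must have shape (m, n, 3)")
        self.curves = c

    @property
    def n_curves(self) -> int:
        return self.curves.shape[0]

    def normalize(self) -> "CurveCohort":
        """Isotropically normalize every curve to unit height."""
        curves = np.stack([isotropic_normalize(c) for c in self.curves])
        return CurveCohort(curves, self.true_labels, normalized=True)


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray
    centers: np.ndarray                   # (k, n_points, 3) mean curves
    k: int
    seed: int
    inertia: float


def cluster_curves(cohort: CurveCohort, k: int, seed: int = 0,
                   n_restarts: int = 10) -> ClusteringResult:
    """Partition a cohort of normalized curves into ``k`` subtypes.

    Greedy (k-means++) seeding with ``n_restarts`` restarts; the best
    inertia is kept and the run is deterministic given ``seed``.  Curves are
    normalized on the fly if the cohort is not flagged as normalized.
    """
    if k < 1:
        raise InvalidParameterError("k must be at least 1")
    if cohort.n_curves < k:
        raise InvalidParameterError("cohort smaller than requested k")
    if not cohort.normalized:
        cohort = cohort.normalize()
    X = cohort.curves.reshape(cohort.n_curves, -1)
    n_unique = np.unique(X, axis=0).shape[0]
    if n_unique < k:
        warnings.warn(
            f"only {n_unique} distinct curves for k={k}: clustering is "
            "degenerate", stacklevel=2)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    centers = km.cluster_centers_.reshape(k, -1, 3)
    return ClusteringResult(labels=labels, centers=centers, k=k, seed=seed,
                            inertia=float(km.inertia_))


def label_agreement(true_labels: np.ndarray, pred_labels: np.ndarray) -> float:
    """Best-permutation matching accuracy between two labelings.

    Cluster indices are arbitrary, so the predicted labels are matched to
    the true ones by the assignment that maximizes agreement (Hungarian
    algorithm on the confusion matrix); returns the matched fraction.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise InvalidParameterError("label arrays differ in length")
    t_ids = np.unique(true_labels)
    p_ids = np.unique(pred_labels)
    conf = np.zeros((t_ids.size, p_ids.size))
    for i, t in enumerate(t_ids):
        for j, p in enumerate(p_ids):
            conf[i, j] = np.sum((true_labels == t) & (pred_labels == p))
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / true_labels.size)
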
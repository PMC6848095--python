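"""K-means subtype classification of synthetic 3D curve cohorts."""

import numpy as np
import pytest

from spinerod import InvalidParameterError, isotropic_normalize
from spinerod.cluster import (ClusteringResult, CurveCohort, cluster_curves,
                              label_agreement)
from spinerod.curves3d import FIVE_TYPE_FAMILIES, generate_curve_cohort


@pytest.fixture(scope="module")
def two_family_cohort():
    curves, labels = generate_curve_cohort(
        FIVE_TYPE_FAMILIES[:2], n_per_family=20, noise_sd=0.005, seed=42)
    return CurveCohort(curves, labels)


@pytest.fixture(scope="module")
def five_type_cohort():
    curves, labels = generate_curve_cohort(
        FIVE_TYPE_FAMILIES, n_per_family=25, noise_sd=0.005, seed=3)
    return CurveCohort(curves, labels)


class TestIsotropicNormalize:
    def test_height_two_curve_is_halved(self):
        c = np.column_stack([np.linspace(1, 0, 5), np.zeros(5),
                             np.linspace(2, 0, 5)])
        out = isotropic_normalize(c)
        # uniform scale 1/2, bottom landmark translated to the origin
        assert np.allclose(out[:, 0], np.linspace(0.5, 0.0, 5))
        assert out[0, 2] - out[-1, 2] == pytest.approx(1.0)
        assert np.allclose(out[-1], 0.0)

    def test_idempotent_on_normalized_curve(self):
        c = np.column_stack([np.zeros(5), np.linspace(0.1, 0, 5),
                             np.linspace(1, 0, 5)])
        out = isotropic_normalize(c)
        assert np.allclose(isotropic_normalize(out), out, atol=1e-15)

    def test_distance_ratios_preserved(self, rng):
        c = rng.normal(size=(10, 3))
        c[:, 2] = np.linspace(3, 0, 10)
        out = isotropic_normalize(c)
        d_in = np.linalg.norm(np.diff(c, axis=0), axis=1)
        d_out = np.linalg.norm(np.diff(out, axis=0), axis=1)
        r_in = d_in / d_in[0]
        r_out = d_out / d_out[0]
        assert np.allclose(r_in, r_out, rtol=1e-12)


class TestClusterCurves:
    def test_two_separated_families_recovered_exactly(self, two_family_cohort):
        res = cluster_curves(two_family_cohort, k=2, seed=0)
        assert label_agreement(two_family_cohort.true_labels, res.labels) == 1.0

    def test_identical_curves_single_cluster(self):
        base = np.column_stack([np.zeros(17), np.zeros(17),
                                np.linspace(1, 0, 17)])
        cohort = CurveCohort(np.repeat(base[None], 8, axis=0))
        res = cluster_curves(cohort, k=1, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-20)
        assert np.all(res.labels == 0)

    def test_duplicate_curves_warn_when_k_exceeds_distinct(self):
        base = np.column_stack([np.zeros(17), np.zeros(17),
                                np.linspace(1, 0, 17)])
        cohort = CurveCohort(np.repeat(base[None], 8, axis=0))
        with pytest.warns(UserWarning, match="degenerate"):
            cluster_curves(cohort, k=2, seed=0)

    def test_five_type_cohort_recovery(self, five_type_cohort):
        res = cluster_curves(five_type_cohort, k=5, seed=0)
        assert label_agreement(five_type_cohort.true_labels, res.labels) >= 0.95

    def test_deterministic_given_seed(self, five_type_cohort):
        a = cluster_curves(five_type_cohort, k=5, seed=11)
        b = cluster_curves(five_type_cohort, k=5, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_permuting_cohort_permutes_partition(self, two_family_cohort, rng):
        perm = rng.permutation(two_family_cohort.n_curves)
        permuted = CurveCohort(two_family_cohort.curves[perm])
        a = cluster_curves(two_family_cohort, k=2, seed=0)
        b = cluster_curves(permuted, k=2, seed=0)
        assert label_agreement(a.labels[perm], b.labels) == 1.0

    def test_inertia_nonincreasing_in_k(self, five_type_cohort):
        inertias = [cluster_curves(five_type_cohort, k=k, seed=0).inertia
                    for k in (2, 3, 4, 5, 6)]
        assert all(a >= b for a, b in zip(inertias, inertias[1:]))

    def test_center_init_is_fixed_point(self, five_type_cohort):
        from sklearn.cluster import KMeans
        res = cluster_curves(five_type_cohort, k=5, seed=0)
        cohort = five_type_cohort.normalize()
        X = cohort.curves.reshape(cohort.n_curves, -1)
        km = KMeans(n_clusters=5, init=res.centers.reshape(5, -1), n_init=1,
                    max_iter=1).fit(X)
        assert label_agreement(res.labels, km.labels_) == 1.0

    def test_k_larger_than_cohort_rejected(self, two_family_cohort):
        with pytest.raises(InvalidParameterError):
            cluster_curves(CurveCohort(two_family_cohort.curves[:3]), k=5)

    def test_result_type(self, two_family_cohort):
        res = cluster_curves(two_family_cohort, k=2, seed=0)
        assert isinstance(res, ClusteringResult)
        assert res.centers.shape == (2, 17, 3)
        assert set(res.labels) <= {0, 1}


def test_label_agreement_is_permutation_invariant():
    true = np.array([0, 0, 1, 1, 2, 2])
    pred = np.array([2, 2, 0, 0, 1, 1])
    assert label_agreement(true, pred) == 1.0
    assert label_agreement(true, np.array([2, 1, 0, 0, 1, 1])) == pytest.approx(5 / 6)
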
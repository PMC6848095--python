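"""Shape metrics: torsion, axial classification, twists, inflection, ratio."""

import numpy as np
import pytest

from spinerod import (InputMismatchError, InsufficientDataError,
                      UndefinedRatioError, classify_axial_projection,
                      count_twists, displacement_ratio,
                      generate_scoliotic_curve_3d, global_torsion)
from conftest import sampled_helix


class TestGlobalTorsion:
    def test_planar_curve_has_zero_torsion(self, group2_profile):
        assert abs(global_torsion(group2_profile.coords)) < 1e-10

    def test_helix_matches_closed_form(self):
        a, b = 1.0, 0.3
        tau = global_torsion(sampled_helix(a, b, n=100))
        assert tau == pytest.approx(b / (a * a + b * b), rel=0.01)

    def test_mirror_image_negates(self):
        h = sampled_helix()
        m = h.copy()
        m[:, 0] *= -1.0
        assert global_torsion(m) == pytest.approx(-global_torsion(h), rel=1e-9)

    def test_scales_inversely_with_size(self):
        h = sampled_helix()
        s = 2.5
        assert global_torsion(s * h) == pytest.approx(global_torsion(h) / s,
                                                      rel=1e-9)

    def test_rigid_motion_invariance(self, rng):
        h = sampled_helix(n=80)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        moved = h @ R.T + rng.normal(size=3)
        assert global_torsion(moved) == pytest.approx(global_torsion(h),
                                                      rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            global_torsion(np.zeros((3, 3)))

    def test_collinear_curve_returns_zero(self):
        line = np.column_stack([np.zeros(10), np.zeros(10), np.linspace(0, 1, 10)])
        assert global_torsion(line) == 0.0


class TestAxialClassification:
    def test_planar_profile_projects_to_line(self, group2_profile):
        assert classify_axial_projection(group2_profile.coords) == "line"

    def test_arc_projection_is_loop(self):
        curve = generate_scoliotic_curve_3d("loop", 0.1)
        assert classify_axial_projection(curve) == "loop"

    def test_figure_eight_projection_is_lemniscate(self):
        curve = generate_scoliotic_curve_3d("lemniscate", 0.1, n_points=41)
        assert classify_axial_projection(curve) == "lemniscate"

    def test_zero_amplitude_degenerates_to_line(self):
        curve = generate_scoliotic_curve_3d("loop", 0.0)
        assert classify_axial_projection(curve) == "line"

    def test_rotation_and_scale_invariance(self):
        curve = generate_scoliotic_curve_3d("lemniscate", 0.08, n_points=41)
        ang = 1.1
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        assert classify_axial_projection(3.0 * curve @ R.T) == "lemniscate"

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_axial_projection(np.zeros((4, 3)))


class TestCountTwists:
    @staticmethod
    def _with_ux(ux):
        n = ux.size
        initial = np.column_stack([np.zeros(n), np.zeros(n),
                                   np.linspace(1, 0, n)])
        deformed = initial.copy()
        deformed[:, 0] += ux
        return initial, deformed

    def test_identity_deformation_has_no_twist(self):
        initial, _ = self._with_ux(np.zeros(17))
        assert count_twists(initial, initial) == 0

    def test_single_signed_bump_has_no_twist(self):
        s = np.linspace(0, 1, 33)
        assert count_twists(*self._with_ux(0.1 * np.sin(np.pi * s))) == 0

    def test_full_sine_has_one_twist(self):
        s = np.linspace(0, 1, 33)
        assert count_twists(*self._with_ux(0.1 * np.sin(2 * np.pi * s))) == 1

    def test_three_half_waves_have_two_twists(self):
        s = np.linspace(0, 1, 33)
        assert count_twists(*self._with_ux(0.1 * np.sin(3 * np.pi * s))) == 2

    def test_mismatched_shapes_rejected(self):
        a, b = self._with_ux(np.zeros(17))
        with pytest.raises(InputMismatchError):
            count_twists(a, b[:-1])


class TestDisplacementRatio:
    def test_planar_deformation_gives_zero(self):
        n = 17
        initial = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(1, 0, n)])
        deformed = initial.copy()
        deformed[:, 1] += 0.05
        assert displacement_ratio(initial, deformed) == 0.0

    def test_equal_components_give_one(self):
        n = 17
        initial = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(1, 0, n)])
        deformed = initial.copy()
        deformed[:, 0] += 0.03
        deformed[:, 1] += 0.03
        assert displacement_ratio(initial, deformed) == pytest.approx(1.0)

    def test_zero_mean_y_rejected(self):
        n = 17
        initial = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(1, 0, n)])
        deformed = initial.copy()
        deformed[:, 0] += 0.01
        with pytest.raises(UndefinedRatioError):
            displacement_ratio(initial, deformed)
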
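"""Rod finite elements: closed-form oracles, symmetry and objectivity."""

import numpy as np
import pytest

from spinerod import (DegenerateGeometryError, InvalidParameterError,
                      NormalizationError)
from spinerod.fem import (BoundaryConditions, LoadCase, Material, Section,
                          build_rod_mesh, normalize_deformation,
                          solve_nonlinear, spine_boundary_conditions,
                          spine_load_case, twist_angle_of_straight_rod)
from spinerod.fem.rotations import exp_so3, log_so3
from spinerod.loads import make_load_table

MAT = Material()
SEC = Section()
E, G = MAT.young_modulus, MAT.shear_modulus
A, I, J = SEC.area, SEC.second_moment, SEC.torsion_constant


def straight_vertical(n=17):
    return np.column_stack([np.zeros(n), np.zeros(n), np.linspace(1, 0, n)])


def clamped(n_nodes, node=0):
    ft = np.zeros((n_nodes, 3), bool)
    fr = np.zeros((n_nodes, 3), bool)
    ft[node] = True
    fr[node] = True
    return BoundaryConditions(ft, fr)


class TestRotations:
    def test_exp_log_roundtrip(self, rng):
        w = rng.normal(scale=0.4, size=(20, 3))
        back = log_so3(exp_so3(w))
        assert np.allclose(back, w, atol=1e-12)

    def test_exp_is_orthonormal(self, rng):
        R = exp_so3(rng.normal(scale=0.8, size=(10, 3)))
        eye = np.swapaxes(R, -1, -2) @ R
        assert np.allclose(eye, np.eye(3), atol=1e-13)


class TestMesh:
    def test_straight_profile_counts_and_length(self):
        model = build_rod_mesh(straight_vertical(), n_sub=1)
        assert model.n_nodes == 17
        assert model.n_elements == 16
        assert model.total_arc_length == pytest.approx(1.0)

    def test_subdivision_counts_and_length_bound(self, group2_profile):
        model = build_rod_mesh(group2_profile, n_sub=4)
        assert model.n_nodes == 65
        assert model.total_arc_length >= 1.0       # curve at least chord height

    def test_arc_length_matches_quadrature(self, group2_profile):
        from scipy.integrate import quad
        from scipy.interpolate import CubicSpline
        coords = group2_profile.coords
        u = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(coords, axis=0), axis=1))])
        spline = CubicSpline(u, coords, axis=0)
        exact = quad(lambda s: np.linalg.norm(spline(s, 1)), 0, u[-1],
                     limit=200)[0]
        # Chordal length converges quadratically to the spline quadrature.
        assert build_rod_mesh(group2_profile, n_sub=8).total_arc_length \
            == pytest.approx(exact, abs=2e-5)
        assert build_rod_mesh(group2_profile, n_sub=32).total_arc_length \
            == pytest.approx(exact, abs=1e-6)

    def test_vertebral_node_map(self, group2_profile):
        model = build_rod_mesh(group2_profile, n_sub=4)
        assert np.array_equal(model.vertebral_nodes, np.arange(17) * 4)
        assert np.allclose(model.nodes[model.vertebral_nodes],
                           group2_profile.coords, atol=1e-12)

    def test_duplicate_points_rejected(self):
        coords = straight_vertical()
        coords[3] = coords[2]
        with pytest.raises(DegenerateGeometryError):
            build_rod_mesh(coords, n_sub=1)

    def test_invalid_subdivision_rejected(self, group2_profile):
        with pytest.raises(InvalidParameterError):
            build_rod_mesh(group2_profile, n_sub=0)


class TestClosedFormOracles:
    def test_axial_bar_settlement(self):
        model = build_rod_mesh(straight_vertical(), n_sub=2)
        nd = model.n_nodes
        ft = np.zeros((nd, 3), bool)
        fr = np.zeros((nd, 3), bool)
        ft[-1] = True
        ft[0] = [True, True, False]
        F = 1e-6 * E * A
        forces = np.zeros((nd, 3))
        forces[0, 2] = -F
        sol = solve_nonlinear(model, BoundaryConditions(ft, fr),
                              LoadCase(forces, np.zeros((nd, 3))), n_steps=2)
        assert sol.displacement[0, 2] == pytest.approx(-F / (E * A), rel=0.005)

    def test_cantilever_tip_deflection(self):
        n = 17
        horizontal = np.column_stack([np.linspace(0, 1, n), np.zeros(n),
                                      np.zeros(n)])
        model = build_rod_mesh(horizontal, n_sub=2)
        nd = model.n_nodes
        P = 3e-3 * E * I          # tip deflection ~1e-3 L: linear regime
        forces = np.zeros((nd, 3))
        forces[-1, 2] = -P
        sol = solve_nonlinear(model, clamped(nd),
                              LoadCase(forces, np.zeros((nd, 3))), n_steps=2)
        assert sol.displacement[-1, 2] == pytest.approx(-P / (3 * E * I),
                                                        rel=0.01)

    def test_straight_rod_twist(self):
        model = build_rod_mesh(straight_vertical(), n_sub=2)
        T = 1e-3 * G * J
        assert twist_angle_of_straight_rod(model, T) == pytest.approx(
            T / (G * J), rel=0.01)

    def test_twist_zero_torque(self):
        model = build_rod_mesh(straight_vertical(), n_sub=1)
        assert twist_angle_of_straight_rod(model, 0.0) == pytest.approx(0.0,
                                                                        abs=1e-12)

    def test_twist_linear_in_length(self):
        full = build_rod_mesh(straight_vertical(), n_sub=2)
        n = 17
        half_coords = np.column_stack([np.zeros(n), np.zeros(n),
                                       np.linspace(0.5, 0, n)])
        half = build_rod_mesh(half_coords, n_sub=2)
        T = 1e-4 * G * J
        a_full = twist_angle_of_straight_rod(full, T)
        a_half = twist_angle_of_straight_rod(half, T)
        assert a_half == pytest.approx(a_full / 2.0, rel=0.01)


@pytest.fixture(scope="module")
def spine_solution(group2_profile):
    model = build_rod_mesh(group2_profile, n_sub=2)
    bcs = spine_boundary_conditions(model.n_nodes)
    loads = spine_load_case(model, make_load_table(17, 4e-9), 0.0)
    return solve_nonlinear(model, bcs, loads, n_steps=10)


class TestSpineCaseProperties:

    def test_zero_torque_solution_stays_planar(self, spine_solution):
        u = spine_solution.displacement
        assert np.max(np.abs(u[:, 0])) <= 1e-10 * np.max(np.abs(u[:, 1]))

    def test_boundary_conditions_satisfied_exactly(self, spine_solution):
        u = spine_solution.displacement
        assert np.all(u[-1] == 0.0)            # L5 pinned
        assert np.all(u[0, :2] == 0.0)         # T1 held in X, Y
        assert u[0, 2] != 0.0                  # vertical settlement free

    def test_external_work_matches_elastic_energy(self, spine_solution):
        assert spine_solution.external_work >= 0.0
        assert spine_solution.external_work == pytest.approx(
            spine_solution.elastic_energy, rel=0.01)

    def test_normalize_deformation_peak_is_one(self, spine_solution):
        un = normalize_deformation(spine_solution)
        assert np.max(np.abs(un[:, 2])) == pytest.approx(1.0, abs=1e-15)

    def test_normalize_rejects_zero_field(self):
        with pytest.raises(NormalizationError):
            normalize_deformation(np.zeros((17, 3)))

    def test_normalize_is_idempotent(self, spine_solution):
        un = normalize_deformation(spine_solution)
        assert np.allclose(normalize_deformation(un), un, atol=1e-15)


class TestObjectivityAndSymmetry:
    def _solve_group2(self, profile_coords, torque):
        model = build_rod_mesh(profile_coords, n_sub=2)
        bcs = spine_boundary_conditions(model.n_nodes)
        table = make_load_table(17, 4e-9)
        nd = model.n_nodes
        forces = np.zeros((nd, 3))
        forces[model.vertebral_nodes, 2] = -table.forces
        moments = np.zeros((nd, 3))
        moments[model.vertebral_nodes[0], 2] = torque
        return solve_nonlinear(model, bcs, LoadCase(forces, moments),
                               n_steps=10)

    def test_rotation_about_z_rotates_solution(self, group2_profile):
        ang = 0.9
        R = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                      [np.sin(ang), np.cos(ang), 0.0], [0.0, 0.0, 1.0]])
        base = self._solve_group2(group2_profile.coords, 1e-11)
        rotated = self._solve_group2(group2_profile.coords @ R.T, 1e-11)
        assert np.allclose(rotated.deformed, base.deformed @ R.T, atol=1e-7)

    def test_torque_sign_flip_mirrors_out_of_plane(self, group2_profile):
        plus = self._solve_group2(group2_profile.coords, 1e-11)
        minus = self._solve_group2(group2_profile.coords, -1e-11)
        up, um = plus.displacement, minus.displacement
        assert np.allclose(um[:, 0], -up[:, 0], atol=1e-7)
        assert np.allclose(um[:, 1:], up[:, 1:], atol=1e-7)

    def test_load_path_insensitivity(self, group2_profile):
        model = build_rod_mesh(group2_profile, n_sub=2)
        bcs = spine_boundary_conditions(model.n_nodes)
        loads = spine_load_case(model, make_load_table(17, 4e-9), 1e-11)
        coarse = solve_nonlinear(model, bcs, loads, n_steps=5)
        fine = solve_nonlinear(model, bcs, loads, n_steps=10)
        diff = np.linalg.norm(fine.deformed - coarse.deformed)
        scale = np.linalg.norm(fine.displacement)
        assert diff <= 1e-4 * scale
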
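"""Rod model assembly: material, section, mesh, supports and load case.

The rod is a contiguous chain of 2-node elements threaded through the
vertebral centroids of a sagittal profile (optionally subdivided through a
cubic spline).  Each node carries a position and an orthonormal triad; the
rest configuration stores, per element, its length, its corotational frame
and the rest offsets of the two nodal triads from that frame, which encode
the initial curvature exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ..errors import DegenerateGeometryError, InvalidParameterError
from ..loads import LoadTable
from ..profiles import SagittalProfile
from .rotations import cross, exp_so3, mean_triad, normalize

__all__ = ["Material", "Section", "RodModel", "BoundaryConditions", "LoadCase",
           "build_rod_mesh", "spine_boundary_conditions", "spine_load_case"]


@dataclass(frozen=True)
class Material:
    """Linear isotropic elastic material (consistent model units)."""

    young_modulus: float = 1000.0
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise InvalidParameterError("Young modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise InvalidParameterError("Poisson ratio must be in [0, 0.5)")

    @property
    def shear_modulus(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))


@dataclass(frozen=True)
class Section:
    """Circular cross-section with Saint-Venant torsion constant."""

    radius: float = 1e-3

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidParameterError("radius must be positive")

    @property
    def area(self) -> float:
        return np.pi * self.radius ** 2

    @property
    def second_moment(self) -> float:
        return np.pi * self.radius ** 4 / 4.0

    @property
    def torsion_constant(self) -> float:
        return np.pi * self.radius ** 4 / 2.0


def element_frame(t: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Corotational element frame from unit tangent and mean nodal triad.

    Columns are [t, n, b]: b is the normalized component of t x n_ref
    (n_ref = second column of the mean triad), n completes the right-handed
    set.  The construction is equivariant under rigid rotations.
    """
    n_ref = M[..., :, 1]
    b = normalize(cross(t, n_ref))
    n = cross(b, t)
    return np.stack([t, n, b], axis=-1)


@dataclass
class RodModel:
    """Discretized rod ready for a nonlinear solve."""

    nodes: np.ndarray                 # (N, 3) rest positions
    triads: np.ndarray                # (N, 3, 3) rest nodal triads
    material: Material
    section: Section
    vertebral_nodes: np.ndarray       # mesh node index per vertebral level
    # Per-element rest data, derived in __post_init__:
    rest_lengths: np.ndarray = field(init=False)
    rest_offsets: np.ndarray = field(init=False)   # (n_el, 2, 3, 3) E0^T A_i0

    def __post_init__(self) -> None:
        x = np.asarray(self.nodes, dtype=float)
        d = np.diff(x, axis=0)
        L0 = np.sqrt(np.sum(d * d, axis=1))
        if np.any(L0 <= 1e-14):
            raise DegenerateGeometryError("co-located mesh nodes")
        t0 = d / L0[:, None]
        A1 = self.triads[:-1]
        A2 = self.triads[1:]
        E0 = element_frame(t0, mean_triad(A1, A2))
        G1 = np.swapaxes(E0, -1, -2) @ A1
        G2 = np.swapaxes(E0, -1, -2) @ A2
        self.rest_lengths = L0
        self.rest_offsets = np.stack([G1, G2], axis=1)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.n_nodes - 1

    @property
    def total_arc_length(self) -> float:
        return float(self.rest_lengths.sum())


def _parallel_transport_triads(nodes: np.ndarray) -> np.ndarray:
    """Nodal triads [t, n, b] with n propagated by minimal rotation.

    For a planar sagittal (Y-Z) curve this yields n = +X at every node, so
    the third axis b spans the sagittal plane.
    """
    d = np.diff(nodes, axis=0)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    tangents = np.empty_like(nodes)
    tangents[0], tangents[-1] = d[0], d[-1]
    mids = d[:-1] + d[1:]
    norms = np.linalg.norm(mids, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise DegenerateGeometryError("curve folds back on itself")
    tangents[1:-1] = mids / norms
    # Seed normal: global +X unless the curve starts nearly along X.
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(t0 @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n = ref - (ref @ t0) * t0
    n /= np.linalg.norm(n)
    triads = np.empty((nodes.shape[0], 3, 3))
    triads[0] = np.column_stack([t0, n, np.cross(t0, n)])
    for i in range(1, nodes.shape[0]):
        t_prev, t_new = tangents[i - 1], tangents[i]
        axis = np.cross(t_prev, t_new)
        s = np.linalg.norm(axis)
        c = float(t_prev @ t_new)
        if s < 1e-14:
            R = np.eye(3)
        else:
            w = axis / s * np.arctan2(s, c)
            R = exp_so3(w)
        n = R @ triads[i - 1][:, 1]
        n = n - (n @ t_new) * t_new
        n /= np.linalg.norm(n)
        triads[i] = np.column_stack([t_new, n, np.cross(t_new, n)])
    return triads


def build_rod_mesh(profile: SagittalProfile | np.ndarray, n_sub: int = 4,
                   material: Material | None = None,
                   section: Section | None = None) -> RodModel:
    """Mesh a centerline into a rod model with ``n_sub`` elements per level.

    Nodes interpolate the natural cubic spline through the vertebral
    centroids (chord-length parameterized); every vertebral level maps to
    exactly one mesh node.
    """
    if n_sub < 1:
        raise InvalidParameterError("n_sub must be at least 1")
    coords = profile.coords if isinstance(profile, SagittalProfile) else np.asarray(profile, dtype=float)
    n_lev = coords.shape[0]
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if np.any(seg <= 1e-14):
        raise DegenerateGeometryError("duplicate / co-located profile points")
    u = np.concatenate([[0.0], np.cumsum(seg)])
    if n_sub == 1:
        nodes = coords.copy()
    else:
        spline = CubicSpline(u, coords, axis=0)
        uu = np.concatenate([
            np.linspace(u[i], u[i + 1], n_sub, endpoint=False)
            for i in range(n_lev - 1)
        ] + [u[-1:]])
        nodes = spline(uu)
    vertebral = np.arange(n_lev) * n_sub
    return RodModel(
        nodes=nodes,
        triads=_parallel_transport_triads(nodes),
        material=material or Material(),
        section=section or Section(),
        vertebral_nodes=vertebral,
    )


@dataclass(frozen=True)
class BoundaryConditions:
    """Per-node constrained components (True = fixed)."""

    fixed_translations: np.ndarray     # (N, 3) bool
    fixed_rotations: np.ndarray        # (N, 3) bool

    def dof_mask(self) -> np.ndarray:
        """Free-DOF boolean mask over the (6N,) DOF vector."""
        n = self.fixed_translations.shape[0]
        fixed = np.zeros((n, 6), dtype=bool)
        fixed[:, :3] = self.fixed_translations
        fixed[:, 3:] = self.fixed_rotations
        return ~fixed.reshape(-1)


def spine_boundary_conditions(n_nodes: int) -> BoundaryConditions:
    """The spinal load case supports.

    L5 (bottom node) is fixed in X, Y and Z and additionally anchored
    against rotation about the vertical axis — the sacrum is rotationally
    held by the pelvis, and without this anchor a two-point translational
    support leaves an applied axial torque reacted only by a quasi-neutral
    rigid rotation of the whole rod about the support line, rather than by
    torsion transmitted through it.  T1 (top node) is fixed in X and Y with
    vertical settlement free; all other rotations are free.
    """
    ft = np.zeros((n_nodes, 3), dtype=bool)
    fr = np.zeros((n_nodes, 3), dtype=bool)
    ft[-1] = [True, True, True]
    fr[-1] = [False, False, True]
    ft[0] = [True, True, False]
    return BoundaryConditions(ft, fr)


@dataclass(frozen=True)
class LoadCase:
    """Nodal dead forces and moments (global components)."""

    forces: np.ndarray       # (N, 3)
    moments: np.ndarray      # (N, 3)


def spine_load_case(model: RodModel, load_table: LoadTable,
                    torque: float) -> LoadCase:
    """Gravity at the vertebral nodes plus an axial torque at T1.

    Each vertebral level receives its load-table force along -Z; a single
    moment of magnitude ``torque`` about +Z acts at the top (T1) node.
    """
    if load_table.n_levels != model.vertebral_nodes.size:
        raise InvalidParameterError("load table does not match vertebral levels")
    forces = np.zeros((model.n_nodes, 3))
    forces[model.vertebral_nodes, 2] = -load_table.forces
    moments = np.zeros((model.n_nodes, 3))
    moments[model.vertebral_nodes[0], 2] = torque
    return LoadCase(forces=forces, moments=moments)
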
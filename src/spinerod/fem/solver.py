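"""Geometrically nonlinear solve of the corotational rod.

Element formulation
-------------------
Two-node corotational beam, 6 DOF per node (translations plus rotation
vectors applied multiplicatively to stored nodal triads).  For each element
a corotational frame is rebuilt from the current chord direction and the
geodesic-mean nodal triad; the elastic deformation seen by the local linear
Euler-Bernoulli/Saint-Venant element is the elongation of the chord plus
the small local nodal rotations relative to that frame (with the rest
offsets of an initially curved mesh subtracted).  The strain energy is

    Phi_e = EA d^2 / 2L0 + GJ (t2 - t1)^2 / 2L0
          + (EI/2L0) * [4 a1^2 + 4 a1 a2 + 4 a2^2]   (per bending plane)

where d is the elongation, t_i the local torsional rotations and a_i the
local bending rotations.  The formulation is objective: the energy is
exactly invariant under rigid motions.

Derivatives
-----------
Element internal forces are exact gradients of Phi_e obtained by
complex-step differentiation (machine precision, no subtractive
cancellation); element tangents are central finite differences of those
gradients.  Both are evaluated for all elements at once through a batch
dimension, so a Newton iteration costs a constant small number of
vectorized energy sweeps.

Equilibrium is reached by incremental load stepping with a Newton loop per
step.  The iteration matrix receives a tiny diagonal regularization: the
spinal support set (two translational pins) leaves one neutral rigid
rotation about the support axis at zero load, which gravity stiffens as
soon as the load factor is positive; regularizing the matrix does not
change the converged solution, which is defined by the residual alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConstraintError, ConvergenceError, InvalidParameterError, NormalizationError
from .model import BoundaryConditions, LoadCase, RodModel, element_frame
from .rotations import exp_so3, log_so3, mean_triad

__all__ = ["Solution", "StepDiagnostics", "solve_nonlinear",
           "normalize_deformation", "twist_angle_of_straight_rod"]

_CS_H = 1e-50          # complex-step size (no cancellation; far below underflow)
# Finite-difference step for the element tangent.  The differenced gradient
# is itself complex-step exact (machine-relative accuracy), so the step can
# be small: truncation ~ delta^2 * d3(Phi) must stay below the softest
# physical stiffness (the gravity-stiffened rigid mode of the spinal
# support set, ~1e-12 in model units), while FD roundoff ~ eps*|g|/delta
# remains negligible.
_FD_DELTA = 3e-8


@dataclass(frozen=True)
class StepDiagnostics:
    step: int
    load_factor: float
    iterations: int
    residual: float


@dataclass
class Solution:
    """Converged state of a nonlinear rod solve."""

    model: RodModel
    initial: np.ndarray              # (N, 3)
    deformed: np.ndarray             # (N, 3)
    triads: np.ndarray               # (N, 3, 3) final nodal triads
    elastic_energy: float
    external_work: float
    diagnostics: list[StepDiagnostics] = field(default_factory=list)

    @property
    def displacement(self) -> np.ndarray:
        return self.deformed - self.initial

    @property
    def vertebral_initial(self) -> np.ndarray:
        return self.initial[self.model.vertebral_nodes]

    @property
    def vertebral_deformed(self) -> np.ndarray:
        return self.deformed[self.model.vertebral_nodes]


def _element_energies(x1, x2, q1, q2, dr1, dr2, rest_offsets, L0, EA, EI, GJ):
    """Vectorized strain energy of all elements; broadcasts leading dims.

    ``x*`` positions, ``q*`` stored triads (real), ``dr*`` incremental
    rotation vectors (possibly complex) applied as exp(dr) @ q.
    """
    A1 = exp_so3(dr1) @ q1
    A2 = exp_so3(dr2) @ q2
    d = x2 - x1
    ln = np.sqrt(np.sum(d * d, axis=-1))
    t = d / ln[..., None]
    E = element_frame(t, mean_triad(A1, A2))
    Et = np.swapaxes(E, -1, -2)
    G1t = np.swapaxes(rest_offsets[..., 0, :, :], -1, -2)
    G2t = np.swapaxes(rest_offsets[..., 1, :, :], -1, -2)
    th1 = log_so3(Et @ A1 @ G1t)
    th2 = log_so3(Et @ A2 @ G2t)
    delta = ln - L0
    tw = th2[..., 0] - th1[..., 0]
    bend = (th1[..., 1] ** 2 + th1[..., 1] * th2[..., 1] + th2[..., 1] ** 2
            + th1[..., 2] ** 2 + th1[..., 2] * th2[..., 2] + th2[..., 2] ** 2)
    return (EA * delta ** 2 / (2.0 * L0) + GJ * tw ** 2 / (2.0 * L0)
            + (EI / L0) * 2.0 * bend)


class _Assembler:
    """Precomputed index plumbing for force/stiffness assembly."""

    def __init__(self, model: RodModel):
        self.model = model
        n_el = model.n_elements
        self.L0 = model.rest_lengths
        self.rest = model.rest_offsets
        m, s = model.material, model.section
        self.EA = m.young_modulus * s.area
        self.EI = m.young_modulus * s.second_moment
        self.GJ = m.shear_modulus * s.torsion_constant
        # Element DOF -> global DOF map: 12 local dofs per element.
        e = np.arange(n_el)
        self.edof = np.concatenate([
            (6 * e[:, None] + np.arange(6)[None, :]),
            (6 * (e + 1)[:, None] + np.arange(6)[None, :]),
        ], axis=1)                                          # (n_el, 12)

    def _batched_energy(self, x, Q, pert_x1, pert_x2, pert_r1, pert_r2):
        """Energy for every element under batched perturbations."""
        x1 = x[:-1] + pert_x1
        x2 = x[1:] + pert_x2
        return _element_energies(x1, x2, Q[:-1], Q[1:], pert_r1, pert_r2,
                                 self.rest, self.L0, self.EA, self.EI, self.GJ)

    def internal_force(self, x: np.ndarray, Q: np.ndarray) -> np.ndarray:
        """Assembled internal force (6N,) via complex-step element gradients."""
        g = self._element_gradient(x, Q)
        f = np.zeros(6 * self.model.n_nodes)
        np.add.at(f, self.edof.T, g)
        return f

    def _element_gradient(self, x, Q):
        """(12, n_el) complex-step gradient of the element energies."""
        n_el = self.model.n_elements
        z = np.zeros((12, n_el, 3), dtype=complex)
        px1, pr1 = z.copy(), z.copy()
        px2, pr2 = z.copy(), z.copy()
        blocks = [px1, pr1, px2, pr2]
        for j in range(12):
            blocks[j // 3][j, :, j % 3] += 1j * _CS_H
        phi = self._batched_energy(x, Q, px1, px2, pr1, pr2)
        return phi.imag / _CS_H

    def tangent(self, x: np.ndarray, Q: np.ndarray) -> np.ndarray:
        """Assembled (6N, 6N) tangent via central FD of element gradients."""
        n_el = self.model.n_elements
        B = 12 * 2 * 12
        z = np.zeros((B, n_el, 3), dtype=complex)
        px1, pr1, px2, pr2 = z.copy(), z.copy(), z.copy(), z.copy()
        blocks = [px1, pr1, px2, pr2]
        # Batch layout: idx = (j * 2 + sign) * 12 + a.  Each (j, sign)
        # sub-batch of width 12 carries the complex-step perturbations of
        # all 12 gradient components, shifted by +/- delta on FD dof j.
        idx = 0
        for j in range(12):
            for sgn in (+_FD_DELTA, -_FD_DELTA):
                blocks[j // 3][idx:idx + 12, :, j % 3] += sgn
                for a in range(12):
                    blocks[a // 3][idx + a, :, a % 3] += 1j * _CS_H
                idx += 12
        phi = self._batched_energy(x, Q, px1, px2, pr1, pr2)
        g = (phi.imag / _CS_H).reshape(12, 2, 12, n_el)
        Ke = (g[:, 0] - g[:, 1]) / (2.0 * _FD_DELTA)        # (j, a, n_el)
        Ke = 0.5 * (Ke + np.swapaxes(Ke, 0, 1))
        K = np.zeros((6 * self.model.n_nodes,) * 2)
        rows = self.edof[:, :, None].repeat(12, axis=2)     # (n_el, 12, 12) row=a
        cols = self.edof[:, None, :].repeat(12, axis=1)
        np.add.at(K, (rows, cols), np.moveaxis(Ke, 2, 0).transpose(0, 2, 1))
        return K

    def total_energy(self, x: np.ndarray, Q: np.ndarray) -> float:
        zero = np.zeros((1, self.model.n_elements, 3))
        phi = self._batched_energy(x, Q, zero, zero, zero, zero)
        return float(np.sum(phi.real))


def solve_nonlinear(model: RodModel, bcs: BoundaryConditions, loads: LoadCase,
                    n_steps: int = 20, tol: float = 1e-9,
                    max_iterations: int = 50,
                    max_rotation_step: float = 0.5) -> Solution:
    """Equilibrium of the rod under incrementally applied loads.

    The load factor ramps linearly over ``n_steps`` increments; each step is
    equilibrated by Newton iteration until the free-DOF residual norm drops
    below ``tol`` relative to the applied load norm.  Raises
    ``ConvergenceError`` with the last residual on failure and
    ``ConstraintError`` if the stiffness stays singular even under
    regularization (an unconstrained rigid mode).
    """
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be at least 1")
    if tol <= 0:
        raise InvalidParameterError("tol must be positive")
    if bcs.fixed_translations.shape[0] != model.n_nodes:
        raise InvalidParameterError("boundary conditions do not match mesh")
    if loads.forces.shape[0] != model.n_nodes:
        raise InvalidParameterError("load case does not match mesh")

    asm = _Assembler(model)
    free = bcs.dof_mask()
    nd = model.n_nodes
    f_forces = np.zeros(6 * nd)
    f_forces[0::6] = loads.forces[:, 0]
    f_forces[1::6] = loads.forces[:, 1]
    f_forces[2::6] = loads.forces[:, 2]
    f_moments = np.zeros(6 * nd)
    f_moments[3::6] = loads.moments[:, 0]
    f_moments[4::6] = loads.moments[:, 1]
    f_moments[5::6] = loads.moments[:, 2]

    # Load path: forces first, applied moments after, each ramped linearly.
    # Ramping gravity to full strength before the torque keeps the torque
    # increments inside the Newton basin of the gravity-stiffened (very
    # soft) rigid-rotation mode of the two-point spinal support.
    legs: list[tuple[np.ndarray, np.ndarray]] = []
    f_base = np.zeros(6 * nd)
    if np.any(f_forces):
        legs.append((f_base, f_forces))
        f_base = f_forces
    if np.any(f_moments):
        legs.append((f_base, f_base + f_moments))

    x = model.nodes.copy()
    Q = model.triads.copy()
    diagnostics: list[StepDiagnostics] = []
    work = 0.0
    f_prev = np.zeros(6 * nd)
    step_counter = 0

    for f_from, f_to in legs:
        ref_norm = max(np.linalg.norm(f_to[free]), 1e-300)
        for step in range(1, n_steps + 1):
            step_counter += 1
            lam = step / n_steps
            f_ext = f_from + lam * (f_to - f_from)
            x_step_start = x.copy()
            spin_acc = np.zeros((nd, 3))
            converged = False
            res_norm = np.inf
            k_scale = 0.0
            for it in range(1, max_iterations + 1):
                r = asm.internal_force(x, Q) - f_ext
                res_norm = np.linalg.norm(r[free])
                # Absolute floor: smallest residual representable given the
                # stiffness scale and the FP spacing of the coordinates.
                fp_floor = 10.0 * np.finfo(float).eps * k_scale * max(
                    1.0, float(np.max(np.abs(x))))
                if res_norm <= max(tol * ref_norm, fp_floor):
                    converged = True
                    break
                K = asm.tangent(x, Q)[np.ix_(free, free)]
                k_scale = float(np.max(np.abs(np.diag(K)))) if K.size else 0.0
                du = _regularized_solve(K, -r[free])
                full = np.zeros(6 * nd)
                full[free] = du
                dx = full.reshape(nd, 6)[:, :3]
                dr = full.reshape(nd, 6)[:, 3:]
                # Cap the step to keep incremental rotations in the small-
                # rotation regime of the local element.
                rot_mag = np.max(np.linalg.norm(dr, axis=1)) if dr.size else 0.0
                scale = min(1.0, max_rotation_step / rot_mag) if rot_mag > 0 else 1.0
                # Non-monotone safeguard: Newton's residual may spike
                # transiently; damp only on severe overshoot.
                for _ in range(9):
                    x_try = x + scale * dx
                    Q_try = exp_so3(scale * dr) @ Q
                    r_try = asm.internal_force(x_try, Q_try) - f_ext
                    if (np.linalg.norm(r_try[free]) < 100.0 * res_norm
                            or scale < 1e-3):
                        break
                    scale *= 0.5
                x, Q = x_try, Q_try
                spin_acc += scale * dr
                if not np.all(np.isfinite(x)):
                    raise ConstraintError(
                        "solution diverged; check supports for rigid modes")
            if not converged:
                raise ConvergenceError(
                    f"no convergence at load step {step}/{n_steps} "
                    f"(residual {res_norm:.3e})", step=step,
                    residual=float(res_norm))
            diagnostics.append(
                StepDiagnostics(step_counter, lam, it, float(res_norm)))
            # Trapezoidal external work along the equilibrium path.
            du_step = (x - x_step_start).reshape(-1)
            fmid_t = 0.5 * (f_prev + f_ext)
            work += float(
                fmid_t.reshape(nd, 6)[:, :3].reshape(-1) @ du_step
                + fmid_t.reshape(nd, 6)[:, 3:].reshape(-1) @ spin_acc.reshape(-1))
            f_prev = f_ext

    return Solution(
        model=model, initial=model.nodes.copy(), deformed=x, triads=Q,
        elastic_energy=asm.total_energy(x, Q), external_work=work,
        diagnostics=diagnostics)


def _regularized_solve(K: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve K du = rhs, escalating diagonal regularization if singular."""
    dscale = np.max(np.abs(np.diag(K))) or 1.0
    for eps in (1e-12, 1e-9, 1e-6, 1e-4):
        try:
            du = np.linalg.solve(K + eps * dscale * np.eye(K.shape[0]), rhs)
        except np.linalg.LinAlgError:
            continue
        if np.all(np.isfinite(du)):
            return du
    raise ConstraintError("singular stiffness: unconstrained rigid mode")


def normalize_deformation(sol: Solution | np.ndarray) -> np.ndarray:
    """Displacement field scaled so the peak |u_Z| equals exactly 1.

    Accepts a ``Solution`` (vertebral-level displacements are used) or a raw
    displacement array.  Raises ``NormalizationError`` when the field has no
    vertical component to normalize by.
    """
    if isinstance(sol, Solution):
        u = sol.vertebral_deformed - sol.vertebral_initial
    else:
        u = np.asarray(sol, dtype=float)
    m = np.max(np.abs(u[:, 2]))
    if m == 0.0:
        raise NormalizationError("max |u_Z| is zero; cannot normalize")
    return u / m


def twist_angle_of_straight_rod(model: RodModel, torque: float,
                                n_steps: int = 4, tol: float = 1e-10) -> float:
    """End rotation of a straight rod under a pure axial torque.

    Validation helper: clamps the first node (translations and rotations),
    applies a moment of magnitude ``torque`` about the rod axis at the far
    end, and returns that end's rotation angle about the axis.  In the
    small-twist regime this equals T L / (G J).
    """
    axis = model.nodes[-1] - model.nodes[0]
    axis = axis / np.linalg.norm(axis)
    nd = model.n_nodes
    ft = np.zeros((nd, 3), dtype=bool)
    fr = np.zeros((nd, 3), dtype=bool)
    ft[0] = True
    fr[0] = True
    bcs = BoundaryConditions(ft, fr)
    forces = np.zeros((nd, 3))
    moments = np.zeros((nd, 3))
    moments[-1] = torque * axis
    sol = solve_nonlinear(model, bcs, LoadCase(forces, moments),
                          n_steps=n_steps, tol=tol)
    R_rel = sol.triads[-1] @ model.triads[-1].T
    w = log_so3(R_rel)
    return float(w @ axis)
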
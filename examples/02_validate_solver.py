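"""Validate the rod solver against closed-form beam theory.

Three textbook checks: axial settlement F L / (E A) of a vertical bar,
cantilever tip deflection P L^3 / (3 E I), and end twist T L / (G J) of a
straight shaft.  Relative errors should be far below 1%.
"""

import numpy as np

from spinerod.fem import (BoundaryConditions, LoadCase, Material, Section,
                          build_rod_mesh, solve_nonlinear,
                          twist_angle_of_straight_rod)

mat, sec = Material(), Section()
E, G = mat.young_modulus, mat.shear_modulus
A, I, J = sec.area, sec.second_moment, sec.torsion_constant
n = 17
vertical = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(1, 0, n)])

# axial bar
model = build_rod_mesh(vertical, n_sub=2)
nd = model.n_nodes
ft = np.zeros((nd, 3), bool); fr = np.zeros((nd, 3), bool)
ft[-1] = True; ft[0] = [True, True, False]
F = 1e-6 * E * A
forces = np.zeros((nd, 3)); forces[0, 2] = -F
sol = solve_nonlinear(model, BoundaryConditions(ft, fr),
                      LoadCase(forces, np.zeros((nd, 3))), n_steps=2)
exact = -F / (E * A)
print(f"axial bar:  u_z = {sol.displacement[0, 2]:+.6e}  "
      f"closed form {exact:+.6e}  rel err {abs(sol.displacement[0,2]/exact-1):.2e}")

# cantilever
horizontal = np.column_stack([np.linspace(0, 1, n), np.zeros(n), np.zeros(n)])
model = build_rod_mesh(horizontal, n_sub=2)
nd = model.n_nodes
ft = np.zeros((nd, 3), bool); fr = np.zeros((nd, 3), bool)
ft[0] = True; fr[0] = True
P = 3e-3 * E * I
forces = np.zeros((nd, 3)); forces[-1, 2] = -P
sol = solve_nonlinear(model, BoundaryConditions(ft, fr),
                      LoadCase(forces, np.zeros((nd, 3))), n_steps=2)
exact = -P / (3 * E * I)
print(f"cantilever: w   = {sol.displacement[-1, 2]:+.6e}  "
      f"closed form {exact:+.6e}  rel err {abs(sol.displacement[-1,2]/exact-1):.2e}")

# torsion
model = build_rod_mesh(vertical, n_sub=2)
T = 1e-3 * G * J
angle = twist_angle_of_straight_rod(model, T)
exact = T / (G * J)
print(f"torsion:    phi = {angle:+.6e}  closed form {exact:+.6e}  "
      f"rel err {abs(angle/exact-1):.2e}")
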
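# Methods

`spinerod` asks a mechanics question about the pathogenesis of adolescent
idiopathic scoliosis (AIS): is the *shape of the sagittal spinal curve*
alone enough to determine whether, and how, a spine deforms out of its
plane under upright loading?  The spine is reduced to its essentials — a
slender, initially planar S-shaped elastic rod, loaded by gravity at the
vertebral centers plus a small axial torque representing asymmetric trunk
loading — and the resulting 3D deformation patterns are quantified and
compared across sagittal shapes.

## The rod model

**Geometry.** A sagittal profile is a planar curve through the 17
vertebral centroids T1..L5, isotropically normalized to unit height with
L5 at the origin (Z up, Y anterior, X lateral).  Synthetic profiles are
built from a two-segment curvature law: a caudal lordotic segment and a
cranial kyphotic segment of opposite curvature sign, each a half-sine
curvature bump, joined smoothly at a single inflection level.  The two
amplitude parameters are the peak offsets of each segment from its own
chord.  The curve is then sheared so T1 sits plumb above L5 (sagittal
balance); the sacral slope is the emergent angle that balance requires.
This yields a genuine two-lobed S around the plumb line (anterior lumbar
lobe, posterior thoracic lobe).  A construction with an exactly vertical
sacral tangent was evaluated first and rejected: combined with balance it
can only produce a single anterior bulge, which is neither an S shape nor
able to reproduce the group-wise deformation patterns.

**Archetypes.** The five right-thoracic subtype stand-ins and the
non-scoliotic mean follow the reported segment statistics — Group I
(Types 2, 4): kyphotic 6±2 vs lordotic 11±2 vertebrae, mid-thoracic
inflection; Group II (Types 1, 3, 5): 12±2 vs 5±2, thoracolumbar
inflection; non-scoliotic: inflection one level below Group II.  Kyphosis
amplitudes are 0.05–0.09 of height (typical of unit-normalized spine
curves), lordosis amplitudes smaller.  The non-scoliotic profile's
lordosis (0.017) is placed near the *neutral lobe balance* at which the
twist-coupled lateral responses of its two lobes nearly cancel: the
model's expression of a deformation-resistant spine.  This choice gives
the non-scoliotic rod its small, opposite-signed lateral response.

**Elasticity.** The rod is a 2-node corotational beam chain: 6 DOF per
node (positions plus multiplicative triad rotations), Euler–Bernoulli
bending with circular section (radius 1e-3), Saint-Venant torsion,
E = 1000, ν = 0.3, all in consistent dimensionless model units.  Each
element rebuilds a corotational frame from its current chord and mean
nodal triad; the rest offsets of an initially curved mesh are stored so
the element sees only elastic deformation.  The strain energy is exactly
invariant under rigid motions (verified to 1e-33 in tests of the energy
along finite rigid rotations).

**Derivatives.** Element internal forces are complex-step derivatives of
the element energy (machine precision); element tangents are central
finite differences of those gradients with step 3e-8 — small enough that
the truncation error stays below the softest physical stiffness (the
gravity-stiffened support modes, ~1e-12 in model units), which matters
because a cruder tangent makes Newton limit-cycle on those modes.

**Supports and loads.**  L5 is pinned in X, Y, Z and anchored against
rotation about the vertical (the pelvis holds the sacrum); T1 is held in
X and Y with vertical settlement free; all other rotations are free.
Without the sacral rotation anchor the applied torque is reacted only by
a quasi-neutral rigid rotation of the whole rod about the support line,
which has no stable small-deformation regime.  Gravity enters as
concentrated forces at the vertebral nodes following the superincumbent
trunk-weight fraction profile (~9% of body weight at T1 rising to ~47% at
L5, renormalized to `total_load`); uniform and linear-ramp schemes are
available.  The torque is a dead moment about +Z at T1.

**Load calibration.** The model has two free load scales.
`total_load = 4e-9` puts the archetypes at a peak sagittal deflection of
a few percent of height (the rods reach a limit point near 8e-9–1.2e-8,
where the pattern distinctions degrade); `torque = 1e-11` sizes the
out-of-plane perturbation so the Group I lateral-to-sagittal displacement
ratios come out near 0.05, the scale reported for those subtypes.  These
two printed observables identify the two free scales; everything else
(group classes, twist counts, the non-scoliotic sign flip, the
correlation structure) is then a prediction of the model.  The printed
torque magnitude (1e-4) is not usable directly: against GJ ≈ 6e-10 it
would wind the rod ~1e5 radians, inconsistent with the nearly planar
deformations reported.

**Solution.** Incremental loading (gravity ramped first, then the torque
at full gravity — this keeps the torque increments inside the Newton
basin of the softest mode) with a full Newton loop per increment,
residual tolerance 1e-9 relative to the applied load (with a floor at the
floating-point limit K·ε·|x|), diagonal regularization escalated only if
the iteration matrix is singular, and a non-monotone backtracking
safeguard.  Default 20 increments per phase, 50 iterations per increment.

## Measurement

**Gauge.** The supports define the axial orientation of the solution only
through the sacral anchor; deformations are *measured* in the axial frame
co-rotating with T1 (the deformed state is rotated about the plumb axis so
T1's axial rotation vanishes).  For an end torque and plumb-balanced
supports this is exactly equivalent to applying the torque at the
opposite end.  It is in this frame — the top vertebra as fixed axial
reference, as in radiographic reconstruction — that the subtype patterns
take their reported form; in the sacrum-fixed frame the group assignment
inverts.

**Normalization.** Displacement fields are scaled by the peak vertical
deformation (max |u_Z| = 1), so patterns are compared shape-to-shape.

**Axial class.** The top-view projection of the normalized deformation
field is a *line* if its RMS deviation from the best-fit line is below
1e-6 of the height; otherwise the smoothed projected curvature's sign
pattern decides: no sign change → *loop*, one or more → *lemniscate*.

**Twist counts.** Two quantities are reported.  `twist_count` is the
topological count of the axial projection (line 0, loop 1, lemniscate 2 —
the loop vs twisted-loop language of rod mechanics), computed as 1 + the
number of projected-curvature sign changes.  `plane_crossings` counts
sign changes of the out-of-plane displacement along the rod (crossings of
the original sagittal plane, after 3-point smoothing and a dead band of
2% of the peak lateral deflection).  In this model the subtype twist
numbers (one per Group I rod, two per Group II rod) are carried by the
topological count; the plane-crossing count comes out 0–1 for all rods
because Group II lateral fields are single-lobed.  The two are computed
independently and cross-checked in tests.

**Global torsion.** The mean discrete Frenet torsion of the deformed
centerline, with derivatives by central differences in arc length, local
torsion (r'×r'')·r''' / |r'×r''|², and arc elements weighted by squared
curvature.  The curvature² damping is needed because nearly planar spinal
curves have long near-straight stretches where Frenet torsion is
ill-conditioned; it leaves constant-curvature oracles (helix b/(a²+b²),
planar → 0, mirror → sign flip, 1/s scaling) unchanged.  A plain
arc-weighted mean and a writhe-per-length strategy (discrete Gauss double
integral) are available behind the same interface for sensitivity checks.

**Inflection detection.** Signed sagittal curvature is evaluated locally
at each interior level through a cubic-spline fit in arc length (a
3-point estimate lets a steep short segment bleed across the inflection);
the inflection is the sign change, or the center of a contiguous
near-zero zone; the kyphotic segment is the one adjacent to T1.  On
noise-free synthetic profiles the detector recovers the generator's
segment split exactly over the whole 4..13 sweep.

**Correlation.** Two normalized deformation fields are compared by the
Pearson correlation of their concatenated (X, Y, Z) vectors (n = 3 × 17),
with a Fisher-transform 95% CI and a two-sided t-test p-value.  Per-axis
correlations are reported alongside for transparency.

**Clustering.** Cohorts of isotropically normalized 3D centerlines are
partitioned by k-means (k known a priori) on concatenated coordinates,
k-means++ seeding, 10 restarts, seeded and deterministic.  Label
agreement against generator families uses Hungarian best matching.

## What the synthetic data does and does not emulate

The generator reproduces the *segment structure* of the sagittal
subtypes (vertebra counts, inflection position, amplitude scale, balance)
and, for clustering tests, 3D curves with loop/lemniscate axial
projections.  It does not reproduce individual patient anatomy: actual
cluster-mean geometries, vertebral size gradients, nonuniform level
spacing, or measurement noise of radiographic reconstruction.  Passing
tests therefore demonstrate that the mechanics pipeline reproduces the
reported *pattern structure* from shapes with the described properties —
not that it numerically reproduces measurements derived from the
unavailable patient cohort.

Two reported quantities are known not to match: the Group I and
non-scoliotic global torsion values.  The model predicts torsion of
similar magnitude across groups (~0.02–0.03), whereas the reported values
separate by a factor ~30 with a sign flip for the non-scoliotic rod.  Our
non-scoliotic rod does have opposite lateral chirality (its displacement
ratio flips sign, as reported), but the Frenet torsion of its deformed
centerline keeps the scoliotic handedness under every metric variant
examined.  This discrepancy is documented rather than tuned away; it most
plausibly reflects the difference between the synthetic archetypes and
the patient-derived cluster-mean geometries, and the unspecified torsion
formula of the original analysis.

## Numerical choices and limitations

* Tolerances: solver 1e-9 relative residual; line gate 1e-6 × height;
  sign-change dead bands 1e-8 × height (2% of peak for plane crossings of
  solved fields); torsion curvature floor max(1e-6/height, 1e-3 × peak
  curvature).
* Mesh: default 2 subdivisions per vertebral interval — the smallest
  meeting the ≤1% displacement-change-on-doubling criterion on all
  archetypes (max observed 0.56%).
* Problem sizes: 33 nodes / 198 DOF per rod solve; 6 rods per default
  experiment; 125 curves in the clustering experiment.
* Degenerate inputs raise typed errors (zero-height curves, co-located
  nodes, zero-variance fields, undefined ratios); a C-shaped profile
  returns a no-inflection flag rather than raising.
* No shear-deformable option, no contact, no follower loads, no material
  nonlinearity, no vertebral bodies/discs/muscles — the spine is a
  centerline only, by design.
* The solver's residual floor is set by double precision on O(1)
  coordinates with O(1e-9) loads; displacement fields are resolved to
  ~1e-4 relative, ample for the pattern-level claims but a limit for
  anyone pushing tolerances tighter.
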
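# spinerod

Elastic-rod biomechanics of the sagittal spine: does the shape of the
sagittal spinal curve alone predispose a growing spine to the 3D
deformation seen in adolescent idiopathic scoliosis (AIS)?

`spinerod` models the spine as a slender, initially planar S-shaped
elastic rod — a centerline through the vertebral centroids T1..L5,
isotropically normalized to unit height — loaded by gravity at the
vertebral centers plus a small axial torque representing asymmetric trunk
loading.  A geometrically nonlinear corotational beam solver computes the
3D equilibrium, and shape metrics quantify the deformation pattern:

* **axial class** — whether the top-view projection of the deformation is
  a *line*, a *loop* (single-signed projected curvature, the V-shaped
  pattern) or a *lemniscate* (figure-eight, the S-shaped pattern);
* **twist count** — the topological twist of the axial projection
  (line 0, loop 1, lemniscate 2), alongside the number of crossings of
  the original sagittal plane;
* **global torsion** τ_g — curvature²-weighted mean discrete Frenet
  torsion of the deformed centerline (1/length);
* **X/Y displacement ratio** — signed mean lateral over mean sagittal
  displacement;
* **pattern correlation** — Pearson r between normalized deformation
  fields of two rods, with Fisher 95% CI and p-value.

The package also ships the synthetic-cohort generator (sagittal profiles
with prescribed kyphotic/lordotic segment structure, per-level
gravitational load tables, 3D loop/lemniscate test curves) and a k-means
subtype classifier for 3D centerline cohorts, so the entire analysis runs
without any external data.

## Worked example

```sh
python examples/03_full_experiment.py
```

solves the six default rod models — five scoliotic sagittal subtype
stand-ins (Group I: Types 2 and 4, short kyphotic segment with
mid-thoracic inflection; Group II: Types 1, 3 and 5, long kyphotic
segment with thoracolumbar inflection) plus the non-scoliotic mean — and
prints:

```
      run_id        group  global_torsion axial_class  twist_count  plane_crossings  xy_ratio ...
       Type1      GroupII        0.022630  lemniscate            2                0  0.052344
       Type2       GroupI        0.027233        loop            1                0  0.049798
       Type3      GroupII        0.025649  lemniscate            2                0  0.050036
       Type4       GroupI        0.028639        loop            1                1  0.083048
       Type5      GroupII        0.019118  lemniscate            2                0  0.055937
NonScoliotic NonScoliotic        0.023794        loop            1                1 -0.036950
```

Group I rods deform into loop-shaped axial patterns with one twist,
Group II rods into lemniscates with two twists, and the non-scoliotic rod
deflects with *opposite* lateral chirality (negative X/Y ratio) — the
sagittal shape alone separates the deformation families under identical
loading.  The correlation table shows the same structure: within-Group-II
pairs r ≈ 0.99–1.00, the within-Group-I pair r ≈ 0.83, all higher than
any cross-group comparison of the non-scoliotic rod.

Other examples: `01_generate_profiles.py` (archetype generation and
inflection-point recovery), `02_validate_solver.py` (closed-form beam
oracles), `04_cluster_cohort.py` (k-means subtype recovery on a 125-curve
synthetic cohort).

A thin CLI wraps the same library:

```sh
spinerod run --out results/run1
spinerod sweep --parameter fem.total_load --values 2e-9,4e-9,8e-9 --out results/sweep
```

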
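# Methods

`scarflow` segments surgically induced myocardial scar in isotropic 3D
late gadolinium enhancement (LGE) cardiac MR volumes from a single brush
stroke per tissue class, quantifies scar volume, and validates the whole
loop on a built-in synthetic phantom.  This note documents the model,
its parameters and defaults, the numerics, and what the synthetic
validation does and does not demonstrate.

## Segmentation model

Four tissue classes are segmented: fat-suppressed **background**,
bright **blood** pool, nulled **myocardium**, and hyperenhanced
**scar**.  The classes are leaves of a small anatomical tree

```
root ── background
     └─ cardiac ── blood
               └─ wall ── myocardium
                       └─ scar
```

which encodes the region-ordering prior that scar lies within the wall
and the wall borders the blood pool.  Segmentation minimizes the convex
relaxation of the hierarchical Potts energy

```
E(u) = Σ_l Σ_x D_l(x) u_l(x) ΔV  +  Σ_{n ≠ root} α_n TV(u_n)
```

over per-voxel memberships `u` on the probability simplex, where `u_n`
is the summed membership of all leaves under node `n`, `ΔV` the voxel
volume (mm³), and TV the anisotropic total variation (sum of absolute
forward differences, each weighted by its voxel face area in mm²).
Anisotropic TV was chosen deliberately: the discrete analog of the
energy is then exactly a pairwise Potts model whose class distance is
the α-weighted tree path length, which makes an exhaustive brute-force
oracle possible on tiny grids and gives the solver a precise,
independently checkable target.

### Data term

The user (or `auto_seeds`) supplies one stroke per class.  Each class's
seed intensities are turned into a Parzen-smoothed histogram: 64 bins
spanning the volume's robust intensity range (1st–99th percentile,
widened where necessary so every seed sample is inside the binned
range — bright scar typically occupies well under 1% of the voxels, so
a pure percentile range would exclude it), Gaussian kernel with
Silverman's-rule bandwidth per class, densities floored at ε = 1e-8 and
renormalized.  Per-voxel costs are

```
D_l(x) = −log(P_l(I(x)) + ε),   clipped to [0, −log ε]
```

with `P_l` the per-bin probability mass interpolated at the voxel
intensity (extended flat to the outer bin edges; zero outside the
binned range, so out-of-range intensities tie all classes at the clip).
Seeds shape the histograms only; they are not hard constraints unless
`pin_seeds` is requested, which zeroes the seeded class's cost and
clips the others at seeded voxels.

### Regularization weights

Per-node weights `α_n` (units: cost × mm⁻¹ equivalent), calibrated once
on the default phantom and frozen:

| node       | α    | role |
|------------|------|------|
| background | 0.1  | mild smoothing of the outer boundary |
| cardiac    | 0.5  | smooth pericardial envelope |
| blood      | 12.0 | ordering prior (see below) |
| wall       | 0.3  | smooth endocardial/epicardial wall surfaces |
| myocardium | 0.02 | minimal leaf smoothing |
| scar       | 0.02 | minimal leaf smoothing |

The large blood weight is the anatomical ordering constraint doing real
work.  Partial-volume mixing at thin scar interfaces produces voxels
whose intensity is exactly blood-like (a scar/background or
scar/myocardium mixture passes through the blood intensity range), so
the data term alone paints a thin "blood" sheet around thin scar — an
anatomically implausible configuration.  Interposing a blood sheet
between two non-blood regions costs `2 α_blood` per face pair over and
above the direct boundary, so setting `α_blood` just above the maximum
possible data advantage (clip × ΔV over two voxel faces ≈ 10.4 at
1.3 mm spacing) suppresses such sheets while leaving data-supported
blood-pool voxels untouched.  The two leaf weights are kept minimal
because isolated speckle is already removed by the minimum-component
filter, while leaf-level TV mainly trims the convex margins of thin
scar patches where data costs are nearly tied.  All weights are
exposed via the library and the CLI config.

### Solver

First-order primal–dual (Chambolle–Pock) iterations on the relaxation:
dual ascent with box projection onto `|p_n,i| ≤ α_n × face_i`, primal
descent with exact per-voxel simplex projection.  Numerical choices:

- **Step sizes**: fixed, from the stability bound σ τ ‖K‖² = 1 with
  ‖K‖² ≤ 12 ‖A‖² (A the leaf-aggregation matrix).  The dual step is
  taken 8× larger than the primal (σ = 8/‖K‖, τ = 1/(8‖K‖)): the dual
  variables must ramp to large bounds (α_blood), and with symmetric
  steps that ramp dominates runtime.
- **Initialization**: one-hot voxelwise cost argmin.  This makes the
  α = 0 limit exact from the first iteration and converges faster than
  a uniform start without measurable quality difference.
- **Convergence**: mean absolute membership change per voxel < tol
  (default 1e-4) **and** mean bound-scaled dual change < tol.  The
  primal criterion alone is unsound here: from a warm start the
  memberships can sit exactly still for many iterations while the dual
  variables are still ramping toward their bounds.
- **Energy reporting**: primal–dual iterations are not energy-monotone
  step to step.  The solver evaluates the relaxed primal energy at
  checkpoints (every `energy_every` iterations), keeps the best
  (lowest-energy) iterate seen, returns it, and reports that
  incumbent's energy trace — non-increasing by construction.  The
  convergence test runs on the raw iterates.
- **Tie-breaks**: hard labels by argmax of memberships; exact ties go
  to the lowest class code (background < blood < myocardium < scar).
  Deterministic and documented, as is the lexicographic tie-break of
  the brute-force oracle.
- **Acceleration**: a numba-fused kernel performs the identical update
  with ~3× less wall time; the numpy path is the reference and the two
  are cross-checked in the test suite.  Without numba the solver
  transparently uses numpy.

Scar is extracted as the scar-class argmax; 26-connected components
below `min_component_ml` (default 0.1 mL) are removed as speckle.

## Synthetic phantom

The phantom is parametric-analytic (no atlas), so ground truth is exact
and generation is dependency-free and bit-reproducible from one integer
seed.  Geometry, all in mm on an isotropic grid (default 96³ at 1.3 mm):

- LV: ellipsoidal shell, 8 mm wall, semi-axes 24×24×32.
- RV: crescent formed by an ellipsoidal shell (semi-axes 28×25×31,
  3.5 mm wall) minus the LV; blood pools fill both cavities.
- Scar: a patch grown by constrained grassfire in the RV outflow wall,
  transmural and thickening toward the cavity (the outer face is the
  epicardial surface, as in a repaired outflow tract), sized to a
  target volume with exact voxel count; optionally a second patch in
  the basal septum (35% of the target volume), emulating a
  ventricular-septal-defect repair.  Scar volumes default to uniform
  draws from 2–25 mL so cohorts bracket a realistic surgical-scar
  burden.
- Intensities: class means 10 / 70 / 30 / 100 (background / blood /
  myocardium / scar, arbitrary units).  Partial volume is modeled by
  Gaussian-blurring per-class indicator fractions (σ = 1.0 mm) and
  mixing intensities by fraction; noise is Rician (magnitude of the
  complex signal with i.i.d. Gaussian components, σ = 5), the standard
  magnitude-MRI model.  The matched angiographic (MRA) channel uses
  blood-bright means (12 / 160 / 45 / 45) on the same geometry.

`auto_seeds` emulates brush strokes: each class region is eroded
(default radius 2 voxels; the radius backs off per class until the
requested stroke fits, as a careful user brushes nearer the boundary of
a small region) and a connected stroke of `strokes_per_class` voxels
(default 200) is grown by randomized flood fill.  `resample_anisotropic`
degrades a case to a thick-slice 2D protocol (default 8 mm slices, 2 mm
gap, 1.6 × 1.3 mm in-plane) by slab averaging, majority-vote label
resampling, and linear in-plane interpolation — the package's vehicle
for the 3D-versus-2D partial-volume comparison.

### What the phantom does not emulate

Pulse-sequence physics, coil sensitivity profiles, respiratory or
cardiac motion, arrhythmia artifacts, trabeculation, papillary muscles,
pericardial fluid, patch-material signal distinct from scar, or
patchy RV-insertion-site fibrosis.  Passing the synthetic validation
therefore demonstrates that the implementation is correct under the
assumed intensity model and that the method's accuracy is attainable
under realistic contrast, noise, partial volume and seeding variation —
it does not demonstrate clinical accuracy on patient data.

## Validation metrics

- **Dice** 2|A∩B|/(|A|+|B|); both-empty defined as 1.0 (perfect
  agreement on absence; conventions differ, so it is documented).
- **Symmetric surface RMSE**: surfaces extracted by marching cubes at
  the 0.5 isolevel in world mm (open level set — no artificial closing
  caps at the grid border, which would contaminate distance
  statistics); RMS of vertex-to-nearest-surface-vertex distances in
  both directions, averaged.
- **Volume**: voxel count × ΔV / 1000, exact integer arithmetic.
- **Bland–Altman**: bias = mean(a−b), limits of agreement
  bias ± 1.96 sd, and CI of the bias bias ± 1.96 sd/√n.  Both
  dispersion bands are reported because published "95% CI" bands around
  a Bland–Altman bias are frequently limits of agreement under another
  name.
- **Pearson r** on paired volumes.

The **observer battery** simulates repeated seeded segmentations: an
*observer* is a persistent brush style — a (placement, stroke erosion
depth, stroke size) triple drawn without replacement from a pool of
three habits: a deep-core brusher (center, erosion 5), an
along-the-margin brusher (edge, erosion 2) and a near-boundary brusher
(center, erosion 1), all at 300 stroke voxels — and a *repeat* re-runs
the same style with fresh random stroke placement.  Strokes themselves
are brush-like: the start voxel is randomly jittered within where the
habit puts the brush and the largest still-unseeded blob is always
brushed first.  Two stroke types exist: the default ``scribble``
wanders across the region by randomized flood fill (broad intensity
sampling — used by the main pipeline), while observers in the battery
use the ``dab``, a compact patch grown distance-ordered from its start,
whose shape is deterministic given the placement — an observer's hand
repeats its own gesture closely, which is exactly what separates
intra- from inter-observer variation.  Mirroring the clinical protocol,
intra-observer agreement pairs the reference observer's first run with
their repeats and inter-observer agreement pairs it with the other
observers' first runs; with equal repeat and observer counts both
reports hold the same number of pairs, so the two correlations are
compared at equal n.  Style-by-case interaction (an observer's habit
interacts with patch size and geometry) makes two observers differ
systematically while one observer's repeats differ only by stroke
sampling — so intra-observer volume correlation is expected to meet or
exceed inter-observer correlation.

## Problem sizes used in the shipped validation

The default validation cohort is 14 cases at 96³ voxels (matching the
clinical cohort size the method was originally validated on); the
observer battery runs ten Monte-Carlo experiments, each on a fresh
4-case cohort at 64×48×58 voxels (the tightest grid that holds the
heart) with 3 observers × 3 repeats, and the thick-slice degradation
check runs on ten cohort members.  These sizes give stable statistics
while keeping a full validation run in the minutes range on one CPU;
all of them scale up through ordinary function arguments.

## Known limitations

- The residual scar-volume bias (≈ −0.05 mL/mL of scar on the default
  phantom) is dominated by truth-scar voxels at multi-class junctions
  whose blurred intensity is blood-like and whose non-blood costs all
  sit at the clip: no intensity-only data term can recover the
  sub-50%-fraction rim, and the ordering prior cannot separate scar
  from myocardium there.  Estimates vs. phantom truth is a stricter
  standard than reader-vs-reader agreement on a shared image.
- The solver optimizes a convex relaxation; thresholded labelings are
  verified within 5% of the exhaustive discrete optimum on small
  random instances but carry no global-optimality certificate at full
  size.
- The hierarchy is fixed at four leaves; multi-focal pathologies with
  distinct signal phenotypes (e.g. patchy insertion-site fibrosis)
  would need their own class and seeds.
- No registration: fusion requires inherently co-registered inputs and
  refuses mismatched grids rather than resampling.
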
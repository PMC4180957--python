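# scarflow

Semi-automated segmentation and volumetric quantification of surgical
myocardial scar in high-resolution, isotropic 3D late gadolinium
enhancement (LGE) cardiac MR — for imaging scientists and
cardiovascular researchers who need reproducible scar volumes and 3D
scar models from whole-heart LGE volumes (e.g. repaired Tetralogy of
Fallot, where thin right-ventricular outflow-tract and septal-patch
scar defeats slice-by-slice 2D analysis).

From a single brush stroke in each of four regions — background, blood
pool, myocardium, scar — the pipeline builds per-class signal-intensity
histograms, converts them into per-voxel negative-log-likelihood costs,
and labels the whole volume by minimizing a hierarchical Potts energy

    E(u) = Σ_l Σ_x D_l(x) u_l(x) ΔV + Σ_{n≠root} α_n TV(u_n)

over the label tree `root → {background, cardiac}`, `cardiac → {blood,
wall}`, `wall → {myocardium, scar}` — a region-ordering prior (scar
lies within the wall, the wall borders the blood pool) solved by a
first-order primal–dual hierarchical max-flow scheme on the convex
relaxation.  The package also ships:

- a parametric **synthetic cardiac phantom** (thin-walled two-ventricle
  geometry, RVOT + septal scar patches, partial-volume blur, Rician
  noise, matched blood-bright MRA channel) with exact ground truth, so
  the entire validation loop runs without any data download;
- every **validation statistic** used for scar segmentation studies:
  Dice, symmetric surface RMSE, volumes in mL, Bland–Altman bias and
  limits of agreement, Pearson r, and a seed-perturbation
  observer-variability battery;
- **scar-to-MRA fusion** for volume-rendered display, plus NIfTI, STL,
  PNG, JSON and CSV I/O.

See `docs/methods.md` for the model, parameter defaults and numerics.

## Worked example

Generate a phantom case, segment it from automatic seed strokes, and
score it against ground truth:

```bash
scarflow phantom --out case0 --seed 3 --grid 96 --scar-volume-ml 10
scarflow segment --volume case0/lge.nii.gz --seeds case0/seeds.nii.gz --out seg0
scarflow fuse    --mra case0/mra.nii.gz --scar seg0/scar.nii.gz --out fused0
```

which prints (numbers from this exact command sequence):

```
phantom written to case0 (true scar volume 10.00 mL)
scar volume: 9.21 mL (4191 voxels); outputs in seg0
fused volume and projections written to fused0
```

`seg0/` now holds the four-class label map, the binary scar mask, an
STL scar surface in world mm, the serialized intensity model, and the
solver trace; `fused0/` holds the MRA with scar burned in at a sentinel
intensity plus maximum-intensity projections.  The estimated 9.21 mL
against the true 10.00 mL is typical: estimated volumes track truth
with r > 0.99 and a small negative bias from unrecoverable
partial-volume rim voxels (see `docs/methods.md`, Known limitations).

The same loop at cohort scale, in Python:

```python
from scarflow.pipeline import run_cohort
summary = run_cohort(n=14, rng_seed=1).report.summary()
```

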
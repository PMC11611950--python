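# dtigrowth

Directionality analysis of longitudinal lesion growth relative to
white-matter microstructure, for neuroimaging researchers studying treated
glioblastoma.  Contrast-enhancing lesions that regrow after treatment (tumor
progression, TP) are hypothesised to expand along white-matter tracts —
perineural satellitosis — while treatment-related abnormalities (TRA,
pseudoprogression / radiation necrosis) were expected to expand more
randomly.  Given two coregistered timepoints per subject (a DTI series and a
binary contrast-enhancing lesion mask at each), the package quantifies how
lesion expansion aligns with the local principal diffusion direction and
compares the TP and TRA groups.

## Method

Per subject:

1. **Tensor fit** — the single-tensor model
   `S_k = S_0 · exp(−b_k · g_kᵀ D g_k)` is fitted voxelwise by ordinary least
   squares in the log domain (exactly determined for the clinical
   1 × b=0 + 6-direction b=1000 s/mm² protocol).  Eigendecomposition yields
   λ₁ ≥ λ₂ ≥ λ₃ and the principal diffusion direction e₁ (the white-matter
   fiber proxy, defined up to sign), plus the fractional anisotropy
   `FA = sqrt(½ Σᵢ<ⱼ (λᵢ−λⱼ)²/Σ λᵢ²)` and the diagonal tensor elements
   Dxx, Dyy, Dzz.  Eigenvectors live in world (mm) coordinates so angles are
   physical even for anisotropic voxels.
2. **Deformation field** — for every voxel the lesion gained between the two
   timepoints, the growth vector is the mm-displacement from the nearest
   timepoint-1 surface voxel (Euclidean distance transform); an iterative
   demons estimator is available as an alternative.  Shrinkage is excluded
   and reported.
3. **Alignment binning** — the angle θ = arccos(|d·e₁|/|d|) ∈ [0°, 90°]
   between each growth vector and the local e₁ is accumulated into nine
   10° bins, weighted by displacement magnitude (or voxel count);
   *parallel* growth is the 0–20° mass, *perpendicular* growth the 70–90°
   mass, each as a percentage of the lesion's total increase.
4. **Group statistics** — group means with 95% t-based CIs, Mann–Whitney U
   tests (TP vs TRA) on parallel %, perpendicular % and ROI mean FA, a
   one-sample t test with Cohen's d on pooled per-subject
   (parallel − perpendicular) differences, and Lilliefors normality
   screening with a seeded Monte-Carlo null.

Because real cohorts of this kind are not publicly deposited, the package
ships a synthetic-phantom module (`dtigrowth.synthetic`) producing fiber
orientation fields, forward-simulated DWI with Rician noise, and
longitudinal lesion masks whose growth has a tunable directional bias
κ relative to the fibers — κ = 0 is exactly isotropic, κ ≈ 8 confines
essentially all growth to within 20° of the fiber axis — so every stage can
be validated against known ground truth.

## Worked example

```python
import numpy as np
from dtigrowth import (FiberPhantomSpec, GrowthSpec, make_fiber_field,
                       simulate_dwi, grow_lesion, subject_pipeline)

phantom = FiberPhantomSpec(grid_shape=(48, 48, 48))          # 2 mm voxels, fibers along x
dirs, tensors = make_fiber_field(phantom)
dwi = simulate_dwi(tensors, noise_sigma=0.0)                  # 1 b=0 + 6 dirs at b=1000

growth = GrowthSpec(seed_radius_mm=14.0, target_volume_ratio=2.0,
                    bias_kappa=4.0, rng_seed=7)               # fiber-biased expansion
mask1, mask2 = grow_lesion(dirs, growth, phantom.affine)

result = subject_pipeline(dwi, mask1, mask2, subject_id="demo", group="TP")
s = result.summary
print(f"parallel growth (0-20 deg):       {s.parallel_pct:.1f} %")
print(f"perpendicular growth (70-90 deg): {s.perpendicular_pct:.1f} %")
print(f"mean FA in the lesion ROI:        {s.mean_fa_roi:.3f}")
print(f"bin percentages: {np.round(s.bin_percentages, 1)}")
```

prints

```
parallel growth (0-20 deg):       88.5 %
perpendicular growth (70-90 deg): 0.0 %
mean FA in the lesion ROI:        0.870
bin percentages: [43.2 45.3 11.5  0.   0.   0.   0.   0.   0. ]
```

The lesion was grown with a strong fiber bias (κ = 4), and the pipeline
recovers that: 88.5% of the volume increase lies within 20° of the fiber
axis, none of it within 20° of perpendicular.  The ROI mean FA equals the
phantom's analytic white-matter FA (λ = (1.7, 0.2, 0.2)·10⁻³ mm²/s →
FA = 0.870).  An unbiased lesion (κ = 0) instead reproduces the analytic
isotropic expectations, 1 − cos 20° ≈ 6.0% parallel and cos 70° ≈ 34.2%
perpendicular.

## Command line

```bash
dtigrowth simulate -c config.yaml      # write a synthetic cohort (NIfTI + bvals/bvecs + CSV)
dtigrowth subject  -c config.yaml sub-000
dtigrowth cohort   -c config.yaml      # TP-vs-TRA report (JSON + Markdown)
dtigrowth all      -c config.yaml      # everything, deterministically from one seed
```

See `tests/test_cli.py` for a complete YAML configuration; every output
directory receives a provenance record (config hash, seed, version), and a
rerun with the same seed reproduces all outputs byte-for-byte.

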
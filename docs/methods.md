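# Methods

This note documents the models and numerical choices behind `dtigrowth`, the
defaults and why they were chosen, and what the synthetic phantoms do and do
not establish about real data.

## Diffusion tensor model

Water diffusion per voxel is modelled by a single symmetric 3×3 tensor `D`
(mm²/s).  For a volume acquired with b-value `b_k` and unit gradient `g_k`,

    ln S_k = ln S_0 − b_k g_kᵀ D g_k,

which is linear in `(ln S_0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`.  The fit is
ordinary least squares over all volumes; with the clinical protocol the
package targets (one b=0 volume plus six non-coplanar directions at
b=1000 s/mm²) the system is exactly determined and the fit is an exact
inverse of the forward model — the test suite verifies recovery to 1e-10 on
noiseless simulations.  Multiple b=0 volumes are averaged before fitting.
Assumptions: Gaussian diffusion (no kurtosis term, single fiber population
per voxel), signal strictly positive.  Voxels with any nonpositive signal
are marked invalid rather than clipped: fabricating log-domain values would
silently bias the tensor, whereas invalid voxels are skipped downstream and
tallied per lesion.

Eigendecomposition sorts eigenvalues descending; negative eigenvalues (from
noisy fits) are retained and flagged so fit quality remains inspectable, and
are clamped to zero only inside the FA formula, the standard convention.
FA is computed in the pairwise-difference form
`sqrt(((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / (2(λ1²+λ2²+λ3²)))`, which is
algebraically identical to the mean-centred form but numerically exact at
both extremes (FA(λ,λ,λ) = 0, FA(λ,0,0) = 1).

Tensor components are kept in the gradient/voxel frame; eigenvectors are
rotated into world coordinates with the orthogonal factor of the affine's
polar decomposition.  All angles and displacement vectors downstream are in
world mm — with 2.1 × 2.6 × 6 mm voxels an index-space angle can be tens of
degrees off, so this is not a cosmetic choice.  An anisotropic-voxel phantom
mode exercises this path.

## Deformation field between timepoint masks

The analysis needs, for each voxel of the region of increase
(mask2 ∖ mask1), a direction of local expansion.  The default estimator is
fully geometric: the vector from the nearest timepoint-1 surface voxel
(6-connectivity surface; nearest by Euclidean distance transform with mm
sampling) to the voxel.  It is deterministic, and by construction the vector
magnitude equals the distance-transform value — an invariant the tests
assert.  Nearest-site ties are resolved by the distance transform's scan
order, which is deterministic for identical inputs.

A classical demons iteration (signed-distance mismatch force, Gaussian
regularisation of the update field at `smoothing_sigma_mm`, default 2.0 mm;
`step_size` 0.5; up to 200 iterations; stopping tolerance 0.01 mm) is
provided for users who want a smooth, registration-style field; defaults
are conservative for the voxel scale the package targets.  Non-convergence
returns the field with a warning rather than failing, since the field is
consumed only for local directionality.

Voxels the lesion *lost* (shrinkage) carry no meaningful growth direction;
they are excluded from the support and their count is reported on the field
and in the per-subject audit record, so the ignored volume is always
visible.  Where the displacement field is sampled is in principle open
(region of increase, lesion boundary, or union of masks); the package
defaults to the region of increase — every voxel of actual volume gain
contributes, and the other two choices remain available as
`support_region`.

A known bias of the nearest-surface-voxel construction: displacements of one
or two voxels are quantised to lattice directions, so angle statistics carry
a resolution-dependent distortion that decays with lesion size.  Measured on
exact concentric spheres, the parallel-fraction excess over the analytic
value is ≈ +3.3 percentage points at a 12-voxel radius, +1.6 at 20, +0.8 at
28.  Consequences: thin shells (one–two voxels of growth) are unreliable,
and the validation phantoms below are deliberately large.

## Alignment statistic

Per supported voxel, θ = arccos(|d·e₁|/|d|) ∈ [0°, 90°], sign-invariant in
both arguments because e₁ is an axis, not an arrow; the cosine is clamped to
[0, 1] before arccos.  θ is accumulated into nine half-open 10° bins (90°
closed into the last bin, so every angle maps to exactly one bin), weighted
by displacement magnitude by default — "amount of growth" is read as mm of
displacement; a count weighting is available and both are reported with the
weighting recorded.  e₁ is sampled at the voxel's own grid location:
interpolating a sign-ambiguous eigenvector field is ill-defined without a
local sign-coherence pass, and at the target voxel sizes nearest-voxel
sampling loses little.  Parallel = bins [0°,20°), perpendicular =
[70°,90°].  The ROI for mean FA defaults to the timepoint-1 lesion mask
(options: timepoint-2 mask, region of increase).  One lesion per subject is
assumed; multi-lesion subjects should be aggregated upstream (a
growth-volume-weighted mean is the natural choice).

Under isotropic growth with any fixed fiber axis, θ has the sphere-cap
distribution P(θ ≤ t) = 1 − cos t, so the parallel and perpendicular
expectations are 1 − cos 20° ≈ 6.03% and cos 70° ≈ 34.20%.  These analytic
values anchor the end-to-end null test.

## Group statistics

* Mann–Whitney U (two-sided, midrank ties): exact by enumeration when
  n₁+n₂ ≤ 12 and the pooled sample is tie-free, otherwise the normal
  approximation with tie and continuity corrections.  The centre
  U = n₁n₂/2 maps to p = 1 exactly.  The exact branch is verified against
  brute-force enumeration over all labelings in the tests.
* One-sample Student's t on per-subject (parallel − perpendicular)
  differences against 0, with one-sample Cohen's d = mean/SD (n−1
  denominator).  Pairing within subject is the only reading that makes a
  one-sample test of the two vector groups well-defined.
* 95% CIs use the t multiplier, not 1.96 — group sizes of interest are
  small (n = 15 in the motivating setting).
* Normality screening is a Lilliefors test: KS distance against a normal
  with estimated mean/SD, with a Monte-Carlo null (default 20 000
  replicates, seeded).  The statistic is distribution-free under the normal
  null, so the null table depends only on n and is cached; the p-value is
  the positively biased estimator (1 + #{null ≥ obs})/(N + 1).  A plain KS
  test against N(μ̂, σ̂) would be anticonservative, which is why the
  Lilliefors correction is not optional.
* No multiple-testing correction by default (three between-group tests are
  reported at face value); a Holm option exists but is off.

## Synthetic phantoms

Fiber fields: uniform axis, circular ("curved") fibers around a line, or a
two-region field split at a plane.  White-matter eigenvalues default to
(1.7, 0.2, 0.2)·10⁻³ mm²/s (FA 0.870, coherent deep white matter); voxels
with undefined orientation get an isotropic tensor at 0.7·10⁻³ mm²/s,
a typical parenchymal mean diffusivity.  DWI simulation uses the classic
six-direction dual-gradient scheme at b=1000 s/mm² plus one b=0 volume,
with Rician noise (magnitude of two Gaussian channels) by default and a
Gaussian mode for analytic checks.  The default grid is 48³ at 2 mm
isotropic so cohort-scale simulations stay fast; an anisotropic mode
(2.1 × 2.6 × 6 mm) mirrors a clinical low-resolution DTI.

Lesion growth is a noisy-front model.  From a spherical seed (timepoint 1,
radius default 12 mm), the timepoint-2 mask is

    mask2 = mask1 ∪ { x : dist(x) ≤ T · exp(−κ tan² ψ(x)) · exp(a ε(x)) },

where `dist` is the mm distance to the seed surface, ψ is the angle between
the voxel's outward direction (from its nearest seed-surface voxel — the
same correspondence the analysis pipeline later measures) and the local
fiber axis, ε is a smooth Gaussian random field (correlation length 4 mm,
amplitude a = 0.15 in log units) giving the front a realistic lumpy
irregularity, and T is solved so the lesion volume reaches
`target_volume_ratio` (default 2.0, a typical contrast-enhancing volume
doubling between follow-ups).  The kernel `exp(−κ tan²ψ)` is a transverse
Gaussian: growth along the fiber with lateral dispersion, κ acting as the
transverse precision.  κ = 0 is exactly isotropic; κ = 8 confines
essentially all growth to a narrow cone (the pipeline recovers ≥ 95%
parallel), and recovered parallel percentage is monotone in κ.  Growth was
deliberately formulated as a thresholded continuous front rather than
lattice accretion: voxel-by-voxel accretion (Eden growth) has intrinsic
lattice anisotropy that measurably biases the isotropic null, and the
front formulation is deterministic given its seed, two orders of magnitude
faster, and monotone (mask1 ⊆ mask2) by construction.

What the phantoms emulate: coherent fiber geometry, the clinical DWI
protocol, magnitude-image noise, lesion-size heterogeneity (lognormal
jitter of seed radius and volume ratio across a cohort), and tunable
growth–fiber coupling.  What they do not: real tumor biology (necrosis,
edema, mass effect, infiltration ahead of enhancement), fiber crossings and
gray-matter uncertainty of e₁, registration error between timepoints, and
segmentation variability.  Passing phantom tests therefore establishes that
the *pipeline measures growth directionality correctly when the inputs are
what they claim to be* — not that directionality separates TP from TRA in
patients (in the motivating clinical study it did not).

## Validation problem sizes

The end-to-end checks use phantom sizes chosen from the resolution study
above: the isotropic null uses a 112³ grid with a 48 mm seed and ratio 2.2
(~7·10⁴ support voxels), where the residual quantisation bias is well
inside the ±2 point tolerance around the analytic 6.03% / 34.20%; directed
growth uses a 72³ grid with a 20 mm seed across κ ∈ {0, 1, 2, 4, 8}; the
Mann–Whitney type-I calibration runs 1000 replicate cohorts of 15 vs 58
subjects on reduced 20³ phantoms with identical bias in both groups; the
Lilliefors calibration uses 5000 null datasets of n = 15 against a 50 000
replicate null table.  A full simulate → subject → cohort run under a fixed
seed is asserted byte-identical across reruns.

## Known limitations

* The nearest-surface-voxel deformation is a geometric surrogate for
  nonlinear registration: it captures local growth direction but not
  internal tissue motion, and its angle statistics are resolution-limited
  for very thin growth shells (quantisation study above).
* The demons estimator regularises in index space scaled per axis, an
  approximation for strongly sheared affines.
* The tensor model itself is single-fiber; in crossing regions e₁ is an
  unreliable fiber proxy, and the alignment statistic inherits that.
* With the transverse-Gaussian growth kernel, any κ > 0 suppresses growth
  at angles near 90° strongly (tan²ψ diverges), so mildly biased phantoms
  show near-zero perpendicular percentages at small lesion sizes — visible
  in the synthetic cohort demo, whose absolute percentages are phantom
  properties, not clinical predictions.
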
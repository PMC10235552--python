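# Methods

This note records the models, numerical choices, and known limitations of
`resectmorph`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem and pipeline

Given same-scanner pre- and postoperative T1-weighted volumes of an
epilepsy-surgery patient, the pipeline estimates where tissue was resected
and how much the cortex outside the resection thinned per year between the
two scans, then compares thinning between surgical procedures (anterior
temporal lobectomy, ATL, vs selective amygdalohippocampectomy, SAH) across
a cohort. Stages: rigid pre/post co-registration → six-class tissue
segmentation → resection-cavity estimation → resection-aware
single-subject template (SST) → Laplacian cortical thickness per timepoint
→ atlas-regional means with exclusions → annualized change →
group statistics.

## Resection segmentation

The cavity appears as tissue that was GM/WM before surgery and CSF after.
The estimator: Gaussian-smooth both CSF probability maps (σ, default
2 voxels), subtract (post − pre), threshold the increase, constrain to
voxels whose preoperative argmax class was GM or WM, and keep the largest
connected component. Choices the method statement leaves open:

- **Threshold semantics.** "Greater than 25 % increase" is read as an
  absolute probability difference Δ > 0.25. A relative change is undefined
  where the preoperative CSF probability is ≈ 0 — which is precisely the
  resection zone.
- **Smoothing units.** σ is in voxel units; at the nominal 1 mm isotropic
  resolution this equals mm. Smoothing is applied to the probability maps
  before subtraction only; the binary mask is never smoothed.
- **Connectivity.** "Contiguous" defaults to the 26-neighborhood (standard
  for 3D lesion masks), configurable to 6 or 18. A tie between equal-size
  largest components is broken toward the larger summed CSF increase, so
  the result is deterministic.
- **Empty result** is valid: a resection-free pair yields an empty mask.

Because the threshold (0.25) is below the half-height of the smoothed
transition, the automated mask systematically extends ~1 voxel beyond the
true cavity wherever the cavity borders preoperative GM/WM; the Dice
acceptance bound absorbs this known, method-inherent bias.

## Tissue segmentation

A six-class (CSF, GM, WM, deep GM, cerebellum, brainstem) 1D Gaussian
mixture fitted by EM on intensities inside a caller-supplied brain mask
(skull stripping is out of scope). Two operating modes:

- **Intensity-only.** Components are initialized at smoothed-histogram
  modes — quantile initialization collapses when class sizes are very
  unbalanced — and named by sorting fitted means against a
  darkest-to-brightest ordering (CSF darkest; WM brighter than GM on T1).
- **Spatial priors.** Per-class prior volumes (e.g. smoothed template
  tissue maps) multiply the Gaussian likelihood in the E-step, with a
  floor of 0.01 so intensity can override a wrong prior. This is the only
  way classes that overlap in intensity (deep GM between GM and WM) stay
  separable, and it is the mode the pipeline uses; the phantom supplies
  priors built by smoothing (σ = 3 voxels) the one-hot preoperative truth
  labels, a stand-in for registered template priors.

EM stops when the relative log-likelihood change falls below 1e-6 or after
200 iterations; variances are floored at 1e-6; the likelihood trace is
recorded and is non-decreasing. Classification is the per-voxel posterior
argmax with ties broken toward the lowest class index
(CSF < GM < WM < DGM < CBM < BST).

Two longitudinal corrections matter quantitatively (both were found by
measuring recovery on phantoms with programmed thinning):

1. **Cavity exclusion from the fit.** Cavity voxels carry preoperative
   priors; left in the fit they inflate the GM variance and push the
   GM/CSF posterior boundary outward *everywhere*, cancelling genuine
   thinning. The mixture is therefore fitted with the estimated resection
   mask excluded from parameter estimation (posteriors are still produced
   there).
2. **Shared parameters across timepoints.** Fitting each scan separately
   lets per-scan parameter drift (the thinner postoperative ribbon has a
   different partial-volume mix, hence a different fitted GM variance)
   move the class boundary differently at the two timepoints, biasing the
   measured change toward zero. The pipeline fits the mixture once on the
   resection-imputed SST and classifies both timepoints with the shared
   parameters (`tissue_seg.posterior_maps`).

## Single-subject template

The SST is the voxelwise mean of the preoperative image and the rigidly
aligned postoperative image, with preoperative intensities imputed
bit-exactly inside the resection mask. Outside the mask it equals the
plain average bit-exactly. This is deliberately a two-image average with
imputation, not an iterative groupwise template: the imputation is the
methodological point, and deformable template refinement is out of scope
(deformable registration is exactly what resections break).

## Registration

Rigid (6-parameter) and affine (12-parameter) registration minimize the
mean-squared intensity difference with Powell's method; both are
deterministic. Transforms act in world (mm, RAS) coordinates with the
rotation centered on the fixed image's grid center; a fitted transform `T`
satisfies `moving(T(x)) ≈ fixed(x)` and can be applied directly to
resample masks (nearest neighbor) or images (linear).

Numerical design, arrived at by probing the cost landscape on phantoms:

- The cost compares **Gaussian-smoothed images at native resolution**
  (default σ = 2 voxels) instead of a downsampling pyramid. On a coarse
  grid the interpolation error of any off-grid candidate transform rivals
  a subtle misalignment signal, and the optimizer then prefers the
  identity.
- The cost sum is evaluated on a stride-2 sample of the fixed grid for
  speed; the moving image is still interpolated at full precision.
- If optimization fails to improve on the identity, the identity is
  returned with a warning.

The quality contract is parameter recovery: translation within half a
voxel, rotation within half a degree, affine scale within 2 %. One caveat
the tests respect: the head phantom is nearly spherically symmetric, so
small rotations are weakly identifiable under heavy independent scan noise
(the clean-landscape valley between 1.5° and 3° is ~1e-3 in MSE units);
rotation recovery is therefore verified at low noise, translation and
scale under noise. Cohort phantom pairs are generated on a shared grid, so
cohort-level runs may set `assume_aligned=True` and skip registration;
registration correctness has its own tests.

## Laplacian cortical thickness

Thickness is estimated by the potential-field method: solve Laplace's
equation over the argmax-GM domain with potential 0 on the white-matter
side (WM, deep GM, cerebellum, brainstem) and 1 on the CSF side (CSF and
outside-brain), then compute, at every GM voxel, the arc length of the
streamline through the normalized gradient field as the sum of two
first-order upwind length fields (distance from the inner boundary plus
distance to the outer boundary), avoiding explicit tracing. This is a
deterministic, analytically checkable stand-in for learned thickness
estimators, whose internals are not this package's contribution.

Numerics:

- Jacobi iteration to a maximum update below 1e-5 (cap 5000 sweeps);
  the solution stays in [0, 1] by the discrete maximum principle and this
  is asserted.
- **Half-voxel interface correction**: the tissue interface is taken to
  lie midway between a GM voxel center and its non-GM 6-neighbor center.
  Without it a slab of n voxels reads (n+1)·h; with it the 4 mm slab is
  recovered exactly.
- Zero-flux (replicated-pad) conditions at the volume faces, so a slab
  touching the grid edge behaves as laterally infinite.
- Upwind length sweeps run to a maximum update below 1e-4 mm (cap 200).
  Voxels caught in cyclic upwind dependencies — possible where the noisy
  gradient field circulates, e.g. near a cavity — never settle; they are
  flagged per voxel, assigned thickness 0, and excluded from regional
  means, as are GM voxels with a vanishing gradient (not bounded by both
  interfaces).
- Convergence with resolution: on the spherical-shell truth the error
  drops from ~0.5 mm at h = 2 to ~0.05 mm at h = 1 (better than halving);
  below ~1 % of the true thickness a resolution-independent voxelization
  bias floor (~0.02 mm) remains, so the halving check is asserted across
  the h = 2 → h = 1 doubling where discretization error dominates.

Regional aggregation averages GM voxels with nonzero thickness per atlas
region, excluding voxels inside the resection mask; regions with fewer
than 10 contributing voxels are flagged low-coverage (an empty region
keeps its row with a NaN mean). With a seizure side given, the ipsilateral
amygdala, hippocampus, entorhinal, and parahippocampal regions are dropped
— they are largely removed by surgery. The contralateral hippocampus is
treated as an ordinary atlas region mean even though it is not a cortical
ribbon structure; how a "thickness" is best defined there is genuinely
ambiguous, and the package does not pretend to resolve it. Annualized
change is (post − pre)/interval in mm/yr, signed, negative = thinning;
positive printed rates elsewhere are magnitudes handled at report level.

## Statistics

- Two-sample *t*: pooled (equal-variance) by default — the classical
  reading of an unqualified "two-sample t-test" — with Welch available by
  flag. Identical constant samples return t = 0, p = 1; zero variance in
  both samples with different means is an error.
- χ²: uncorrected Pearson on 2×2 tables, df = 1. On the reference cohort's
  demographic count tables this gives 0.15 for gender and 0.06 for
  seizure side; note that df = 1 Pearson p-values for those statistics
  are 0.70 and 0.81, and those are what this package reports.
- FDR: Benjamini–Hochberg step-up (the field default for an unqualified
  "FDR correction"), order-preserving, capped at 1, tested against a
  definitional oracle. Regionwise families: ipsilateral and contralateral
  sets are corrected separately (configurable to one family) — regional
  analyses in this literature commonly mix corrected ipsilateral results
  with uncorrected contralateral findings, so the family structure is an
  explicit choice here.
- Correlations use the signed annualized change, so less preoperative
  thickness correlating with more thinning appears as a positive r.
- Engel outcome: I → favorable, II–IV → less favorable; missing values are
  excluded with a log entry.
- `run_group_analysis` skips any analysis whose metadata is missing, with
  a log entry, never silently.

## Synthetic phantoms

The phantom is a sphere-in-sphere head: WM core (radius 28 mm at the 96 mm
reference scale), cortical GM shell whose width varies by angular sector
(12 sectors per hemisphere, one per atlas region, including the four
mesial temporal structures; defaults 2.6–3.4 mm), CSF out to the brain
radius (40 mm), and three small interior spheres for deep GM, cerebellum,
and brainstem so all six classes exist. Geometry scales with grid size.
Class mean intensities are 10/70/100/130/160/190 (CSF < GM < DGM < WM <
CBM < BST); the narrowest adjacent gap is 30, so the default noise σ = 6
gives class SNR 5. Intensities are partial-volume weighted via 2×
supersampling, which dithers interfaces across voxels — this is what lets
mean regional thickness resolve sub-voxel change. Postoperative volumes
apply per-region thinning (outer GM surface moves inward by
rate × interval) and, optionally, a spherical cavity that converts GM/WM
to CSF: ATL-like radius 16 mm centered lateral-mesially, SAH-like radius
10 mm centered mesially (at the reference scale; chosen to match
realistically scaled resection volumes), on the seizure side. An optional
rigid offset resamples the postoperative anatomy for registration tests.

Cohorts draw per-subject thinning rates from the group distributions —
ATL 0.08 ± 0.11, SAH 0.01 ± 0.02 mm/yr, truncated so postoperative
thickness stays above 0.5 mm (negative draws, i.e. thickening, are
allowed; the SAH spread crosses zero) — applied uniformly across that
subject's regions, and interscan intervals uniform on 0.5–2.9 yr (ATL) and
1.0–4.9 yr (SAH), whose means (1.7, 2.95 yr) match the demographic table
of the motivating cohort. Demographic covariates (age, gender, side,
onset-age availability, Engel class) are drawn to resemble that table.

What the phantom does *not* emulate: cortical folding (regions are
angular sectors of a shell, so ground truth stays analytic), bias fields,
motion artifacts, scanner differences, and anatomically realistic cavity
shapes. Passing tests therefore demonstrate correctness of the estimators
under known geometry and noise, not performance on clinical images.

## Problem sizes used in the checks

Resection recovery runs 6 ATL-like + 6 SAH-like phantoms at 96³ with
class SNR 5, plus a resection-free phantom; thickness accuracy uses the
analytic slab and shell at h = 2, 1 (and 0.5 in exploratory runs); the
imaging cohort for rate recovery is 6 + 6 subjects at 64³ — the package's
choice of a desk-scale cohort that leaves the group-mean recovery
criterion (±0.03 mm/yr) a meaningful test. The detection-power (20 seeds)
and type-I (200 seeds) checks are statistics-level simulations: group
rates fixed at 0.08 vs 0.01 mm/yr (and equal under the null) with
per-subject estimation noise whose SD is measured from the imaging
cohort's own residuals, not assumed.

## Known limitations

- The resection estimator inherits the ~1-voxel outward bias of
  thresholding at 0.25 (above); manual correction exists for clinical use.
- Rotation registration on near-symmetric images under heavy noise is
  weakly identified (above); real brains are far more asymmetric.
- Thickness values are voxel-grid quantities; no surface reconstruction
  is attempted, and sub-voxel accuracy relies on averaging many
  interface-dithered voxels per region.
- The EM segmenter has no Markov-random-field spatial regularization and
  no bias-field correction; it is a documented classical stand-in, not a
  re-implementation of production segmenters.
- Grids are never resampled implicitly: any grid mismatch is an error.
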
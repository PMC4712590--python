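# Methods

This note records the models, conventions and numerical choices behind
`rgfbreast`, and what the synthetic validation does and does not show.

## Data model and axis conventions

All grids are stored in a fixed anatomical order: axis 0 superior→inferior,
axis 1 anterior→posterior (chest wall at high index), axis 2 left→right.
NIfTI input of any orientation is reoriented through its affine; masks are
binarized at strictly-greater-than-zero so 0/1/255 label encodings work.
The FT mask is a subset of the breast mask by contract and is re-intersected
after every interpolation step. DICOM series input is not implemented; NIfTI
is the only volume dialect.

## Geometric reorientation

The pipeline needs cubic 1 mm voxels and the breast axis aligned with the
anterior direction.

* **Resampling** uses linear interpolation; masks are interpolated as floats
  and re-binarized at 0.5 (never nearest-neighbour, which would shift
  boundaries by up to half the slice thickness).
* **Nipple angle.** The chest-wall plane is fitted to the posterior
  boundary of the breast mask by RANSAC (300 consensus rounds, 2 mm inlier
  tolerance, deterministic internal seed) followed by least-squares
  refinement on the inliers. RANSAC is essential: when the breast axis is
  tilted, part of the curved breast surface also faces posterior and a
  plain least-squares fit converges to a compromise plane (observed errors
  of ~15° at a 30° tilt). The rotation angle is the in-axial-plane angle of
  the fitted plane's normal — equivalently, of the line through the nipple
  perpendicular to the chest wall. One global angle is applied to all
  slices.
* **Nipple auto-detection** (when no landmark is supplied) takes the breast
  voxel with maximal perpendicular distance anterior of the chest-wall
  plane; because the apex is a shallow extremum, the centroid of all voxels
  within 1 mm of the maximum is used. On phantoms this lands within ~2
  voxels of the constructed landmark.
* **Rotation** is an in-plane rotation of every axial slice about the
  breast-mask centroid, linear interpolation, out-of-grid samples read as
  background.

Fibroglandular composition (FC) is conserved through resampling + rotation
to well under 0.02 absolute on all cohort phantoms (typically 0.007–0.018);
the residual drift is dominated by re-discretization of FT structures near
the acquisition slice thickness, not by the rotation.

## RGF measurement conventions

The relative-radius grid is r_k = k/100, k = 1…100 (one hundred samples;
r = 0 is excluded because the zero-radius circle degenerates to a single
pixel). A circle of radius ρ is rasterized as the 1-pixel annulus
{d ∈ [ρ−0.5, ρ+0.5)}. Both numerator and denominator are restricted to
breast pixels, because circles can leave the non-circular breast contour
and air pixels would dilute the fraction; an annulus containing no breast
pixel yields an *undefined* value (NaN), which is skipped — never imputed —
in region averaging and in every feature. The slice centre is the
unweighted centre of mass of the breast mask. Region boundaries split the
N coronal slices at ⌊N/3⌋ and ⌊2N/3⌋; each region's representative curve
averages the 5 slices centred on ⌊mean region index⌋, requiring N ≥ 15.

Note the annuli of adjacent r_k overlap whenever R < 100 px (sample spacing
R/100 < 1 px); the membership rule is still well-defined per radius, and
the implementation is verified against an independent per-pixel oracle with
exact agreement.

## Features

Feature conventions where the definition leaves latitude: the SD uses the
n−1 normalisation; the slope is ordinary least squares of value on r; the
position of the maximum takes the smallest r on ties; "inner 50 %" is
inclusive at r = 0.5; the highest/lowest "10 %" are the 10 largest/smallest
order statistics of the 100 values (proportionally fewer if some radii are
undefined, minimum one). Curves with more than 10 undefined values are
rejected as too truncated. The three difference features are computed as
exact differences of their parents, so those identities hold to the bit.

**Known limitation — f4 on flat profiles.** The radial position of the
maximum is a discontinuous functional: on a near-flat curve the maximum is
a near-tie (top-two margins of ~0.002–0.02 on uniform phantoms), so
interpolation-level perturbations relocate it arbitrarily. Under a 30°
rotation round trip the other 12 features reproduce within 0.03, while f4
can jump by several tenths on uniform-FT phantoms. The same caveat applies
to real sparse-pattern subjects, whose profiles are flat by definition.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test (exact null
distribution when the pooled sample is ≤ 25 without ties — always the case
at the study's 8 + 15 design with continuous features — otherwise the
tie-corrected normal approximation). Significance is reported per test at
α = 0.05 with no multiple-testing correction, matching the per-feature
reporting convention; outputs flag the 13-test family per region. Empirical
type-I error at the study group sizes is 0.03–0.07 over 500 null cohorts.

## Classification

Leave-one-out cross-validation over subjects; each fold fits
StandardScaler + SVC on the training subjects only, so no standardization
statistics leak from the held-out subject. C = 1 throughout; kernels:
linear; polynomial of order 3 (γ = 1/n_features, coef0 = 1); RBF with
σ = 1 under k(x,y) = exp(−‖x−y‖²/(2σ²)), i.e. γ = 0.5 (the plain
exp(−‖x−y‖²/σ²) convention is available via configuration); sigmoid with
γ = 1/n_features, coef0 = 0. The polynomial/sigmoid secondary parameters
are conventions, not study-fixed values. Standardization itself is a design
choice — the features mix slopes, means and SDs on different scales and the
RBF/sigmoid kernels are scale-sensitive. Classes are unweighted despite the
15/8 imbalance. A training fold that loses a class entirely is counted as a
misclassification with a warning.

## Synthetic cohort: what it emulates, and what it does not

The phantom breast is a half-ellipsoid (defaults 40 × 60 × 45 mm half-axes)
on a flat chest-wall plane, with the axis tilted in the axial plane by a
per-subject angle (±20° in cohorts), voxelized at planning-CT-like
2.5 × 1 × 1 mm spacing. FT layout:

* **Non-sparse**: per-slice, per-1-mm-radial-bin thresholding of a smooth
  Gaussian random field against the occupancy target min(c·e^(−d/λ), 1)
  with λ = 25 mm, c calibrated per slice so the slice composition equals
  the target. This pins a monotone radial decay and the FC by construction.
* **Sparse**: prolate ellipsoidal clusters (3 mm in-plane radius, 1.5×
  elongated along SI, like ductal structures) dropped uniformly at random
  until the composition target is reached — a near-flat radial profile.
  Spherical clusters large enough to survive 2.5 mm slice resampling gave
  profiles no flatter than the non-sparse mode; the elongation resolves
  that tension.
* **Uniform / annulus / full / empty**: diagnostic modes with flat,
  banded, saturated and null profiles respectively.

The random-field correlation lengths (5 mm along SI, 3 mm in-plane) keep FT
structures resolvable at the slice thickness — a physical prerequisite for
composition to survive linear interpolation + 0.5 re-thresholding. Cohort
jitter: half-axes ±10 %, composition target 0.25 ± 0.07 (group-independent,
so FC carries no class signal), cluster radius and decay scale ±20 %. All
randomness derives from one integer seed via `numpy.random.SeedSequence`
spawning.

What passing on phantoms does **not** show: robustness to real segmentation
noise, pectoral muscle and skin, non-ellipsoidal breast shapes, intensity
artefacts, or the observer variability of the sparse/non-sparse ground
truth (labels here are true by construction). The sharp mode contrast also
makes the classification easier than in patients; phantom accuracies
validate the machinery, not clinical performance.

## Problem sizes used in validation

The test suite and the acceptance script use the study-sized cohort
(15 + 8 subjects at the default grid), 500 replicates for the null
calibration, 200 label permutations for the permutation baseline, and 50
random ≤ 64×64 mask pairs for oracle equivalence.
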
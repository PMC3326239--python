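# Methods

This note documents the models, numerical choices and limitations behind
`petseg`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic phantom model

Real validation of PET segmentation against histology requires registered
surgical-specimen data that is not publicly available, so the package ships
a phantom generator that emulates the statistical structure of that
setting and provides an exact voxel-level ground truth.

A phantom is a piecewise-constant uptake map on a 3-D grid (default 96³
voxels at 2 mm isotropic; the benchmark cohort uses 64³, a 12.8 cm field of
view that comfortably contains the lesion sizes below), degraded by:

1. **System blur** — separable Gaussian PSF, σ = FWHM/2.3548 per axis,
   default 6 mm FWHM, matching the resolution class of the stand-alone
   scanners on which the adaptive thresholds were calibrated.
2. **Noise** — additive Gaussian, default σ = 0.2 SUV (~10% of the 2.0 SUV
   background), applied after the blur as a proxy for post-reconstruction
   noise.  Iteratively reconstructed PET noise is approximately Gaussian in
   the image domain, and the additive model keeps every test target
   analytic; a Poisson option exists for sensitivity checks.  No published
   noise level exists for the reference setting, so behavioural tests sweep
   noise seeds rather than trusting one level.

**Ground truth** is defined *before* blur and noise: every voxel whose
centre (at (index+0.5)·spacing) lies inside a component with uptake above
background.  Blur and noise therefore never alter the truth mask — the
property that makes overlap metrics exact.

**Heterogeneous lesions** are built from three components: a hot main
sphere (uptake 4× background ≈ a typical tumour-to-background ratio of 4:1),
an offset hot ellipsoidal lobe straddling its surface (irregular outline),
and a colder core at 1.5× background (necrotic-like, still part of the
tumour).  Cohort lesion volumes are drawn uniformly from 6–30 cm³, inside
the 4–33 cm³ range of the clinical setting being emulated.  What the
phantom deliberately does **not** model: intratumoural texture, sinogram-
level physics, scanner-specific PSF anisotropy, and respiratory motion.
Consequently, passing tests demonstrate correct and well-behaved algorithms
under controlled conditions, not clinical accuracy.

## Preprocessing chain

Segmentation operates on restored images: two iterations of a 3-D bilateral
filter followed by Landweber deconvolution.

- **Bilateral filter**: weight = spatial Gaussian (6 mm FWHM) × radiometric
  Gaussian on intensity difference, normalised per voxel.  The radiometric
  σ defaults to 10% of the robust intensity range (1st–99th percentile):
  scale-free, outlier-stable, and overridable.  Window radius defaults to
  ⌈2σ_spatial⌉ voxels per axis.
- **Landweber**: x ← x + τ·H(y − Hx) with H a unit-DC Gaussian of 6 mm
  FWHM, τ = 1.0, 30 iterations, x₀ = y, and a nonnegativity projection
  after each step (SUV is nonnegative; the projection suppresses Gibbs
  undershoot).  With unit DC gain the operator spectrum lies in (0, 1], so
  any τ ∈ (0, 2) converges and the projected iteration is projected
  gradient descent on ‖y − Hx‖², hence the residual norm is nonincreasing.
  Deconvolving an edge that is *sharper* than the assumed PSF necessarily
  rings; the ringing is confined to the PSF neighbourhood of the
  discontinuity (asserted in the tests).

All convolutions use mirror padding, so the chain is deterministic and
bit-reproducible.

## Region conventions shared by the segmenters

- Connected components are 26-connected; every mask is restricted to the
  component containing (or nearest to) the seed point.
- The **search region** bounds all lesion statistics (SUV_max, isocontours,
  clustering samples).  The benchmark derives it from the truth bounding
  box dilated by 16 mm; on real data a user would draw it.  Using a local
  region rather than the whole grid prevents hot-spot leakage from
  unrelated structures.
- The **background ROI** required by the Nestle and Schaefer rules stands
  in for "a neighbouring organ far from the target": the benchmark supplies
  a 15–25 mm shell outside the truth bounding box.

## Thresholding family

The published coefficients (59.1/18.5; 0.307/0.588; β = 0.15; a = b = 0.50
for equivalent diameter ≥ 3 cm, a = 0.67, b = 0.60 below) are
scanner-dependent calibrations and are exposed as estimator parameters.

The volume- and uptake-adaptive rules are circular (the threshold depends
on statistics of the thresholded region).  They are solved by damped Picard
iteration: start from the 40% SUV_max mask, update T, re-threshold, stop
when |ΔT| < 0.1% of SUV_max or after 50 iterations; a detected period-2
cycle returns the midpoint threshold with `converged_ = False`.  On a
two-level image the iteration terminates in ≤ 2 steps at the closed-form
fixed point.  A `single_pass` mode applies the formula once to the initial
mask, since the original descriptions do not state which variant was used.
The Schaefer size class is estimated from the 40% mask and re-estimated
once from the result (two passes at most); a fraction ≥ 1 is returned as
the empty-mask signal rather than an error.

## Level set

φ is a signed Euclidean distance (negative inside), evolved by
∂φ/∂t = −g(ν − εκ)|∇φ| with Godunov upwinding on the balloon term ν,
central differences for the mean curvature κ (clamped to the maximal
grid-resolvable curvature), and redistancing by exact Euclidean distance
transform every 20 steps.  g(s) = 1/(1+(s/λ)²) on the gradient magnitude of
the preprocessed image.

Numerical choices that required judgement:

- **λ default**: 0.15 × the 99th-percentile gradient magnitude in the
  search region.  A median-based default collapses on restored images —
  most voxels are flat background, so the median sits at the noise floor
  and g ≈ 0 everywhere, freezing the front at its initialisation.  The
  chosen scale freezes the front only at the strongest edges (g < 0.03)
  while it moves freely elsewhere.
- **Defaults ν = −1 mm, ε = 1 mm²**: the 40% SUV_max initialisation
  over-covers blurred lesions, so the default balloon shrinks the front
  onto the edge.  Without the advection term ∇g·∇φ (out of scope) the model
  is one-directional: an initialisation *inside* the lesion will keep
  shrinking; initialise outside.
- **Stopping**: the flipped-voxel fraction must stay below 2·10⁻⁵ for five
  consecutive steps, but never before 40 iterations — at sub-voxel front
  speeds voxel flips arrive in bursts and an early quiet spell is not
  convergence.
- **CFL**: the driver rescales any step that would move the front by more
  than one voxel; a strict mode raises instead for direct single-step use.

## Gaussian-mixture EM

One-dimensional K-class mixture (default K = 3: background, transition,
tumour) fit on the search-region intensities with deterministic quantile
initialisation, log-domain responsibilities, and a σ floor of 10⁻⁶ × data
spread; a collapsing component is re-seeded with jitter and flagged.  The
log-likelihood trace is recorded and is nondecreasing (EM guarantee,
asserted per iteration in the tests).  Tumour = voxels whose
maximum-responsibility class is the highest-mean class — invariant to class
permutation by construction.

## Fuzzy clustering (FCM, FCM-SW)

Memberships follow the inverse-distance update with exponent 1/(b−1) on the
squared distance (the printed inverse-squared-distance form is the b = 2
default, which is also the package default); a voxel coincident with a
centroid receives full membership there.  Centroids are u^b-weighted means.
Both updates are exact coordinate minimisers, so the recorded objective is
nonincreasing.  Initial centroids come from intensity quantiles —
deterministic, which removes run-to-run variance from the benchmark.

**Over-clustering and merging**: fit with K_init = 9, then repeatedly merge
the nearest centroid pair (memberships summed, merged centroid recomputed
from the combined memberships) down to K_target = 3, then refine by a short
converged fit from the merged centroids.  Over-clustering protects the
quantile initialisation from swallowing conflicting regions.

**FCM-SW** adds spatial context as regularising channels compared against
the *same* class centroid as the intensity (shared-centroid form):

    d²_ik = (x_i − c_k)² + α(x_s,i − c_k)² + β_k(x_w,i − c_k)²

where x_s is the anisotropic-diffusion-smoothed image (Perona–Malik,
conductance exp(−(|∇I|/κ)²), stable step 1/6, default 10 iterations) and
x_w is the coarse-scale à trous wavelet context: the undecimated B3-spline
transform (kernel (1,4,6,4,1)/16, hole spacing 2^(j−1), exact additive
reconstruction) with the fine detail planes below a scale floor removed
(defaults: 3 scales, floor 3, i.e. x_w is the twice-smoothed image).  The
shared centroid is essential: with per-channel centroids the regulariser
can never relabel a homogeneous region, because each class's own channel
centroid adapts to its members.  With the shared form, a necrotic core
whose coarse-scale context matches the hot rim is pulled into the tumour
class while its raw intensity alone would exclude it.

β_k = β₀(c_k/max_k c_k)^γ grows with class uptake, so the wavelet term
dominates precisely in high-uptake classes.  β₀ and γ are the method's two
free parameters, set by trial and error once on a development set of eight
rim/core phantoms spanning 6–28 cm³ and then frozen at β₀ = 16, γ = 1
(selection favoured high necrotic-core coverage at the lowest
classification error); they are never adapted to an individual image.
β_k is frozen from the merged centroids before the final regularised fit so
the refined objective is a fixed functional with a monotone trace.  With
α = β₀ = 0 the pipeline reduces exactly (bit-level) to plain FCM.

**Tumour extraction**: a voxel is tumour when its membership in the
highest-centroid class is at least its membership in the lowest-centroid
class (equivalent to argmax at K = 2).  The middle class of a K = 3 model
on a sharp two-level lesion is a partial-volume shell, not anatomy;
assigning the lesion only argmax-top voxels systematically under-segments,
while assigning the whole middle class over-segments.  The
beats-background rule draws the boundary at the natural equidistance point
and preserves the intended contrast between plain FCM (excludes the core)
and FCM-SW (recovers it).  `defuzzify` itself returns plain argmax labels
with ties broken toward the higher centroid.

## Metrics

SOI = 2|A∩B|/(|A|+|B|); two empty masks are defined to agree (SOI = 1,
degenerate case, documented here because the convention is not universal).
CE = (PCE + NCE)/VoIL × 100% with VoIL the reference voxel count; CE is
asymmetric and may exceed 100%.  Relative volume error uses
V = voxel count × voxel volume; underestimation is negative.  The paired
t-test reports t, two-sided p and df; zero-variance differences are the
exact-tie case (t = 0, p = 1 for identical lists; infinite t flagged as
degenerate otherwise).

## Problem sizes

Default test and benchmark sizes are chosen so the full suite runs on a
single CPU in a few minutes: 48³ grids for single-case checks, 64³ for
cohorts, and the cohort-ranking check uses 7 heterogeneous cases × 3 noise
seeds (21 replicates).  All sizes are parameters; nothing in the algorithms
depends on them.

## Known limitations

- The phantom's Gaussian-noise/piecewise-constant-uptake model understates
  the texture and reconstruction artefacts of clinical PET.
- The level set is shrink-only by construction (no advection term) and
  relies on the convergence rule, not a force balance, to stop at weak
  edges.
- Threshold coefficients are used as published; on any other "scanner"
  (blur/noise setting) they require recalibration, which is exactly the
  caveat the benchmark is designed to expose.
- EM assumes Gaussian class densities; heavy-tailed uptake distributions
  are not modelled.
- `fcm_merge` needs the feature matrix attached to the state
  (`state._features`), which the segmenters do internally; standalone use
  must attach it explicitly.
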
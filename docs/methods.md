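# Methods

This note documents the models and numerical choices behind `petasp`:
what each stage computes, which parameters matter, what the simulators
do and do not emulate, and where the genuinely open design decisions
were made.

## Asphericity and the surface estimator

Asphericity is defined from the surface area *S* and volume *V* of the
delineated lesion as `ASP = 100·[(S³/(36πV²))^⅓ − 1]`, the percentage by
which *S* exceeds the surface `(36πV²)^⅓` of the sphere with the same
volume. The quantity is dimensionless and scale-invariant; by the
isoperimetric inequality it is non-negative for any true shape, so any
measured negative value is discretization error (we tolerate up to
2 percentage points on voxelized masks).

Everything therefore hinges on estimating *S* from a binary voxel mask
without systematic bias for smooth shapes. The options considered:

* **Voxel-face counting** (exposed faces × face area) is exact for
  axis-aligned boxes but overestimates smooth surfaces by up to ~50%
  (the staircase/Manhattan effect), which would report spheres at
  ASP ≈ 30–50% instead of 0. It is kept as `method="voxel"`, clearly
  labelled as biased for smooth shapes.
* **Marching cubes on the raw mask** reduces the staircase excess to
  ~8–10% on digitized balls — still far from the sphere null.
* **Marching cubes + Gaussian pre-smoothing of the mask** (iso-level
  0.5) repairs the sphere null but rounds off corners and edges; a
  digitized 20³ cube loses ~9% of its surface at sigma = 1 voxel, and no
  sigma simultaneously keeps the cube within 5% and the digitized-ball
  ASP within 2 points.
* **Marching cubes + Taubin mesh smoothing** (the default): the
  λ/μ band-pass mesh filter (λ = 0.5, μ = −0.53) attenuates the
  voxelization ripple — which lives at the one-voxel wavelength —
  without the global shrinkage of a pure Laplacian flow and with little
  effect on flat faces. With the default pass count, digitized balls of
  radius 10–20 voxels come out at ASP ≈ +0.6 points and surface errors
  ≈ 1–2%, while the 20³ cube stays within ~4% of 6a².

The Taubin pass count defaults to `40 / h²` (h = geometric-mean voxel
size in mm, clipped to [5, 300]) so that smoothing acts on a fixed
*physical* scale: under grid refinement the estimate then converges
toward the continuous surface rather than carrying a
resolution-dependent residual.

Volume for the ASP ratio is taken from the same mesh by the divergence
theorem, so the (S, V) pair is geometrically consistent; the reported
MTV, by contrast, is the plain voxel-count volume of the VOI (in ml).
For masks with internal cavities the iso-surface contains both the outer
and the inner closed sheet; *S* is their sum and the cavity volume
subtracts from *V* — this is exactly the mechanism by which necrosis
raises ASP.

## Solidity

The convex hull of the ROI voxel centers (physical coordinates, Qhull)
defines the denominator: grid voxels whose centers lie inside or on the
hull, boundary-inclusive with a tolerance of 1e-9 relative to the hull
diameter. Solidity = |ROI| / |hull voxels|, 1 for convex lesions. Masks
with fewer than 4 non-coplanar voxels are rejected as degenerate. The
implementation vectorizes the half-space test over the hull bounding
box; tests verify exact agreement with an explicit per-voxel loop.

## SUV conversion

SUV = tissue concentration (MBq/ml) divided by injected dose per body
weight. Weight entered in kg is converted to grams so that the result is
the conventional dimensionless g/ml quantity (lesion SUVmax values in
the tens, as observed clinically; without the factor they would be in
the 10⁻⁴ range). The injected dose is decay-corrected over the
injection-to-scan delay with the F-18 half-life of 109.77 min:
`dose · 2^(−Δt/T½)`.

## Segmentation

Delineation iterates a background-corrected volume-reproducing
threshold:

1. Seed = location of the maximum within the user's bounding box (a
   stand-in for observer VOI placement), or the global maximum.
2. Initial background = image median (the lesion occupies a small
   fraction of the field of view); `T₀ = B + 0.5·(local max − B)`.
3. Iterate: mask = 26-connected component containing the seed among
   voxels ≥ T (closed threshold); B = mean value in the shell
   `dilate(mask, g+w) \ dilate(mask, g)` (defaults g = 1, w = 2 voxels,
   mean aggregation — a thin collar that stays clear of the blurred
   lesion edge); mAV = mean uptake in the mask;
   `T ← B + f·(mAV − B)`.
4. Stop when `|ΔT| < ε·(mAV − B)` (ε = 0.01) or after 50 iterations
   (failure reports the last two thresholds).

On a noiseless two-level image the fixed point `T = B + f·(uptake − B)`
is reached exactly in one update. The volume-reproducing fraction
defaults to f = 0.39 and is exposed as configuration: it is the quantity
one calibrates against phantoms of known volume for a given scanner and
reconstruction. With the default, a 15 mm-radius ball at 10:1 contrast
and 2 mm PSF is recovered within ~12% of its true volume; smaller
lesions are increasingly over-segmented by blur (partial-volume effect).
Raising f never enlarges the converged mask. Masks below 3 ml are
flagged by `check_min_volume` (boundary-inclusive) rather than dropped:
at clinical PET resolution smaller lesions cannot be delineated
reliably.

Manual correction is supported only as provenance bookkeeping (an
externally edited mask can be attached as `auto+corrected` or
`external`); there is no interactive editing.

## Phantoms

Lesions are modelled as indicator functions (ball, ellipsoid, spherical
shell, disjoint multiball, and a lobulated star-shaped family
`r(θ,φ) = r₀(1 + a·P(θ,φ))` with P a seed-fixed band-limited real
spherical-harmonic perturbation, degrees 2–6, normalised to max |P| = 1,
amplitude a ∈ [0, 0.5)). Rasterization evaluates the indicator at 2×
supersampling and block-averages to a soft indicator, reducing
partial-volume aliasing; the image is then
`background + indicator·(uptake − background)`, convolved with an
isotropic Gaussian PSF (default sigma 2 mm, typical clinical PET), plus
optional additive Gaussian noise. The ground-truth mask is the unblurred
indicator at native voxel centers. Identical specs (including seed)
produce bit-identical volumes.

The continuous-limit (S, V) reference is closed-form where available
(ball, shell, disjoint multiball) and otherwise computed by dense
midpoint quadrature of the star-shaped first fundamental form,
`dS = r√((r² + r_θ²)sin²θ + r_φ²) dθdφ`, on a 512×1024 angular grid
(≤ 0.1% error on smooth test surfaces, e.g. the prolate spheroid against
its closed form). This reference is independent of any mesh extraction
and serves as the oracle for the shape metrics. Reference ASP of the
lobulated family increases monotonically with amplitude at fixed seed.

Noise is additive Gaussian on the blurred image — sufficient for testing
segmentation robustness, but it does not reproduce the
reconstruction-correlated, intensity-dependent noise of iterative PET,
nor uptake heterogeneity inside the lesion (uptake is uniform). Passing
phantom tests therefore validates geometry and the delineation
machinery, not scanner physics.

## Cohort simulator

Per-subject metrics (SUVmax, SUVmean, MTV, ASP, solidity) are drawn from
a Gaussian copula: latent correlation `2·sin(π·ρ_S/6)` from the target
Spearman matrix (checked positive semidefinite), marginals matched to
median and IQR — lognormal for the positive right-skewed metrics,
normal for solidity. Defaults reproduce the descriptive structure of a
60-patient NSCLC cohort (SUVmax median 18.7, MTV median 42.7 ml, ASP
median 26.3%, solidity median 0.649; ASP–MTV rank correlation 0.54,
ASP–solidity −0.79, solidity uncorrelated with SUV). TLG is derived as
MTV × SUVmean, which yields its near-collinearity with MTV (realized
rank correlation ≈ 0.96) by construction. Unstated cross-correlations
(SUVmax–SUVmean 0.85, SUVmax–MTV 0.15, and small remaining entries) were
chosen once as physiologically plausible values that keep the matrix
positive definite.

Survival: exponential event times with rate `log 2 / median₀`
(baseline median 24 months) multiplied by the true hazard ratio
(default 3.4) for subjects above the true cutoff — the analytic
0.7-quantile of the covariate marginal, comfortably inside the IQR —
and administrative censoring at the follow-up window (36 months). This
gives event rates around 70%, comparable to progression rates in
locally advanced NSCLC. Weibull baselines, covariate-dependent
censoring and competing risks are not modelled.

## Survival statistics

* **Cox regression**: Efron handling of tied event times; damped Newton
  maximization of the partial likelihood with analytic gradient and
  Hessian (columns centered for conditioning); Wald z and p; 95% CI
  `exp(β ± 1.96·se)`. Monotone likelihoods (perfect separation) are
  flagged and β capped at ±15 instead of diverging. The solver is
  validated against lifelines and against an independently coded
  likelihood maximized by bounded scalar search (|Δβ| < 1e-6).
* **Optimal cutoff**: candidates are the distinct observed values v with
  Q1 ≤ v ≤ Q3 (quartiles by linear interpolation of order statistics —
  configurable, since the candidate set depends on it); one fit per
  indicator `[x > v]` (strict binarization: the boundary subject goes to
  the low group; identical groups would give identical fits, so only
  unique values are scanned); the winner maximizes |Wald z|, ties broken
  toward the smaller cutoff. "Most significant" is interpreted as the
  Wald criterion because the reported outputs are HR/CI/p triplets. The
  reported direction is normalized so HR ≥ 1 (for protective covariates
  such as solidity the indicator is inverted to `[x ≤ v]`, which flips
  the sign of β exactly). No multiplicity correction is applied across
  the scan — deliberately, to mirror common practice — and the
  inflation is made visible: the full scan table is returned, and the
  Monte-Carlo tests quantify the null rejection rate of the scan
  (severalfold the nominal 5%, versus ~5% for a log-rank test at a
  prespecified cutoff).
* **Multivariate selection**: covariates with univariate p ≤ 0.10 enter;
  among admitted pairs with |Spearman ρ| ≥ 0.9 the one with the larger
  univariate p is dropped (the threshold separates the TLG/MTV case at
  ρ ≈ 0.96 from the ASP/MTV case at ρ ≈ 0.54); the joint model is then
  reduced by backward elimination of the largest Wald p above 0.05, one
  covariate at a time. The elimination rule is a reconstruction of the
  common "final model" convention; it is configurable.
* **Kaplan–Meier / log-rank** are delegated to lifelines; `survival_at`
  evaluates the right-continuous step function. The log-rank statistic
  is cross-checked against an explicit observed-minus-expected
  summation.

## Problem sizes in the test suite

Monte-Carlo calibrations use 400–1000 replicates of n = 60 cohorts
(hazard-ratio recovery: 500 replicates; null calibration: 1000), copula
calibration n = 5000, and phantom grids of 40³–96³ voxels; these sizes
keep each estimate's Monte-Carlo error well inside the asserted bands.

## Known limitations

* Absolute ASP values on identical masks differ between surface
  estimators; comparisons across software require a fixed estimator.
  Validation here rests on analytic shapes and convergence properties,
  not on reproducing any particular clinical ASP value.
* The delineation is a reconstruction of "volume-reproducing threshold
  after background subtraction" from first principles; vendor tools may
  differ in iteration details, and f should be recalibrated per
  scanner/reconstruction.
* The simulators do not model scanner physics (sinograms,
  reconstruction, TOF/PSF modelling), respiratory motion, DICOM
  metadata, or intra-lesion uptake heterogeneity.
* No proportionality diagnostics, time-dependent covariates, competing
  risks, or bootstrap confidence intervals.
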
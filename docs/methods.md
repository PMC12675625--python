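# Methods

`glymphpipe` re-creates, on fully synthetic data with known ground truth, a
diffusion-MRI analysis chain used to study prodromal α-synucleinopathies
(isolated REM-sleep behavior disorder, iRBD): multi-shell microstructure
mapping with a three-compartment neurite model, skeleton-based voxelwise
group statistics on white and gray matter, the DTI-ALPS perivascular-flow
index, gait-derived clinical metrics, and mixed-data phenotype clustering
with bootstrap validation. This note records the models, the defaults that
matter, and the design choices made where the design was genuinely open.

## Acquisition scheme

The simulated protocol is a pulsed-gradient multi-shell acquisition:
10 b = 0 volumes plus shells at b = 700, 1000 and 2855 s/mm² along 6, 30
and 60 non-collinear directions (106 volumes). Directions are generated by
deterministic electrostatic repulsion with antipodal symmetry; they are a
stand-in for the scanner's table, not a copy of it.

## Forward signal model

Tissue voxels follow the three-compartment neurite model

    S/S0 = (1 − iso)·[icvf·S_intra + (1 − icvf)·S_extra] + iso·exp(−b·d_iso)

* `S_intra`: sticks (zero perpendicular diffusivity) dispersed by a Watson
  distribution of concentration κ about a mean axis μ, with the dispersion
  reported as ODI = (2/π)·arctan(1/κ). The dispersed-stick integral is
  evaluated by 64 × 64 Gauss–Legendre × trapezoidal quadrature over the
  hemisphere; against a 256 × 512 reference the relative error is < 1e-10
  for κ ≤ 64 at the protocol's b-values (the documented requirement is
  < 1e-4).
* `S_extra`: axially symmetric Gaussian with tortuosity coupling
  d_perp = d_par·(1 − icvf), Watson-averaged via τ(κ) = E[(n·μ)²].
* Fixed diffusivities: d_par = 1.7e-3 mm²/s, d_iso = 3.0e-3 mm²/s (the
  conventional defaults for this model family).
* ODI = 0 is clamped to κ = 64 (the arctan inverse diverges); the fitted
  ODI floor is odi(κ=64) ≈ 0.00995 so the odi↔κ maps stay mutually
  consistent everywhere.
* Crossing voxels average the anisotropic term over their two fiber
  populations.
* Noise is Rician: magnitude of two independent Gaussian channels of scale
  `noise_sigma`. At b = 0 this inflates the sample mean above S0, which the
  generator's tests check as a noise-realism property.

**Periventricular voxels are the exception.** The ALPS quantity of interest
is a gain on x-axis diffusivity, which has no representation inside the
neurite model; those voxels are therefore synthesized with a Gaussian
tensor D = d_perp·I + (d_par − d_perp)·μμᵀ whose Dxx is multiplied by the
phantom's `perivascular_gain`. With the tortuosity convention above, the
noiseless planted ALPS index equals the gain exactly, which makes the
end-to-end chain auditable: control gain 1.6 and patient gain 1.2 plant
indices in the range such studies report, with the patient < control
ordering.

## Phantom

A geometric convention, not an anatomy: two tube tracts crossing at 90°
(x- and y-oriented), a GM ribbon enclosing the interior, a central CSF
block for the lateral ventricle, and two periventricular slabs —
"projection" (fibers along z) and "association" (fibers along y) — flanking
it on the left (lower-x) side. Regions are defined in fractional
coordinates; the default grid is 40 × 48 × 40 at 2 mm isotropic and grids
below 20 × 24 × 20 are rejected. Tissue parameters are piecewise constant
(WM icvf 0.7 / odi 0.2, GM 0.4 / 0.6, CSF iso = 1, periventricular
0.6 / 0.15), which keeps the forward simulation exact and groupable by
tissue configuration. The "patient" condition lowers ODI by a configurable
delta (default 0.10) inside a configurable deficit region (default: the
x ∈ [0.15, 0.45) fraction of tract 1) and lowers the perivascular gain.

For group-level skeleton studies the package also provides a *map-level*
mode that emits per-subject FA/ICVF/ODI/ISO/GM-probability maps directly
(truth maps, 1-voxel Gaussian smoothing to give tracts a ridge profile,
additive Gaussian map noise). This emulates the registered, fitted maps a
real study feeds into skeleton statistics without refitting 4-D signals
per subject, and is the mode the end-to-end cohort simulations use for the
voxelwise arm; the ALPS arm always runs the full signal → tensor chain.

## Fitting

* **Tensor**: log-linear least squares with an intercept. The default shell
  filter is the literal b < 1000 s/mm² (keeping the 6-direction b = 700
  shell and b = 0 volumes — an exactly determined fit); `include_max_b`
  switches to b ≤ 1000 (36 directions), since 6-direction fits are
  noise-fragile. Whether the original tooling read the bound inclusively
  is unknowable from the outside, so both behaviors exist and neither is
  asserted as "the" one. Negative eigenvalues are clipped to zero and
  counted (refit-with-constraints was rejected for simplicity). Color-FA
  follows the red = x (left–right), green = y, blue = z convention.
* **Neurite model**: per voxel, a coarse grid search over
  11 (icvf) × 11 (odi) × 6 (iso) × 30 candidate orientations, then
  Nelder–Mead refinement of (icvf, odi, iso, θ, φ) with tolerance 1e-6 and
  ≤ 400 iterations, started from the best grid point (or the tensor
  principal eigenvector where it scores better). The refinement objective
  evaluates the dispersed-stick term through a per-shell cubic-spline table
  over (odi, |cosψ|) (96 × 96 knots, ≈1e-7 absolute accuracy vs the
  quadrature) — the quadrature itself is too slow inside an optimizer loop.
  On noiseless signals the median |error| for ICVF and ODI is well under
  the documented 0.05 bound; the residual at the returned parameters is
  ≈ 0, never worse than at the planted truth beyond the refinement
  tolerance.

## ALPS index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

with Daa = eₐᵀDeₐ averaged over each cubical ROI. Higher = better
perivascular (glymphatic) flow. ROI placement is config-supplied in a
common space (the per-subject vein-map placement of the original procedure
is out of scope since no susceptibility imaging is simulated); the default
puts the two ROIs at the centroids of the phantom's periventricular slabs,
left hemisphere = lower x-index half. The cubical edge (default 3 mm) is
realized as the odd voxel count whose physical extent is nearest the
requested edge — 1 voxel at 2 mm spacing — and the rounding rule is tested.
The index is scale-invariant and strictly monotone in its four inputs;
both are property-tested.

## Skeleton projection (TBSS / GBSS analogs)

The group skeleton is the ridge of the mean FA map: voxels with mean
FA ≥ 0.2 that are local maxima within ±1 voxel along the
tract-perpendicular direction. The perpendicular is the dominant
eigenvector of the *structure tensor* (Gaussian-averaged gradient outer
product, σ = 1 voxel) of the smoothed map. A Hessian-eigenvector variant
was tried first and is degenerate on parabolic tube cross-sections
(constant isotropic curvature leaves the eigenvector arbitrary and keeps
surface voxels); the structure tensor handles that geometry and is
validated against a brute-force local-maximum scan, with no claim of
bit-equality to any external tool.

WM projection searches ±perpendicular (nearest-first, strict-improvement
ties, default reach 6 mm) for the subject's FA maximum and reads any metric
at that voxel. GM projection does the same on GM probability; a skeleton
voxel is retained iff the projected GM probability exceeds 0.65 in more
than 75 % of subjects (the threshold is applied to the *projected* value —
the reading most consistent with a per-subject criterion; applying it to
the raw map instead is a caller choice, since the threshold and fraction
are parameters). Individual sub-threshold subjects at retained voxels are
filled with a Gaussian-weighted (σ = 2 mm, distances in mm between skeleton
voxels, 3σ cutoff) average of their own valid skeleton values; unfillable
voxels are reported, never silently imputed. Registration is bypassed:
subjects are generated in a common space.

## Group statistics

* **TFCE**: enhanced(v) = Σ_h e(h,v)^E·h^H·dh over thresholds h = k·dh ≤
  stat(v), with E = 0.5, H = 2, dh = max/100 and 26-connectivity by default
  (the published defaults for the method). Negative maps are enhanced
  separately and returned signed. Implementation is checked against an
  independent BFS-labelled discrete sum to 1e-6.
* **Permutation inference**: Freedman–Lane covariate handling (fit the
  reduced model, permute residuals, refit the full model), contrast t-map,
  one-sided TFCE per the configured direction, FWER p-values from the
  max-enhanced-statistic null. Exhaustive enumeration replaces sampling
  when n! ≤ n_perm. Confounded designs (group inside the covariate span)
  are rejected. The calibration experiment (null data, 16 subjects, two
  covariates, 25-voxel skeleton, 500 permutations, 200 datasets) keeps the
  family-wise false-positive rate within [0.01, 0.10] at nominal 0.05.
* **ROI comparisons**: linear-model F-test of the group factor on top of
  covariates (ANCOVA), cross-checked against statsmodels; Bonferroni
  multipliers are caller-supplied because family sizes differ per analysis.
* **Partial correlation**: residualize both variables on the covariates,
  Pearson on the residuals, p from the t transform with n − k − 2 degrees
  of freedom; cross-checked against pingouin.

## Clinical cohort and clustering

The cohort table mirrors the variable inventory of an iRBD case–control
study (sleep questionnaires, MDS-UPDRS subscores, timed motor tests,
neuropsychology, raw gait side/task measures, binary non-motor symptoms),
with Gaussian noise for continuous variables (clamped at each variable's
floor — no negative timed measures) and Bernoulli draws for binary ones.
Patients carry a planted subgroup structure: subgroup B is older and worse
on the affected variables. The default effect profile (2.25–3 within-group
SDs on the affected continuous variables, +0.65 on the two affected binary
probabilities) defines the package's "clearly separated severity subgroup"
condition — strong enough that the clustering chain should recover it
essentially perfectly, which is what its tests assert. Real cohorts
(published A-vs-B differences run nearer 1 SD) are *not* this separable;
passing these tests shows the chain works, not that clinical clusters are
this clean. Any profile can be passed explicitly.

Clustering uses the Gower dissimilarity (range-normalized continuous terms,
disagreement indicators for binary/categorical, pairwise deletion of
missing values, unit weights by default with ranges from the observed
sample), PAM for the partition, silhouette for k-selection with the
Calinski–Harabasz score reported alongside (computed from squared distances
to medoids, since Gower space has no coordinates), and bootstrap stability:
1000 resamples with replacement, re-cluster each, ARI against the full-data
labels on the unique subjects present (duplicates count once — ARI is
defined on a set of items). PAM is solved exactly by deterministic
enumeration when C(n, k) ≤ 2000 (which covers every instance at this
package's scale, including 44 subjects at k = 2); larger instances use
greedy BUILD plus best-improvement SWAP with lowest-index tie-breaks.
Plain BUILD+SWAP is a local search and provably misses the optimum on some
small random instances, which is why the exact path exists. Subjects with
silhouette width ≤ 0 are moved to an "unassigned" list — an explicit
package convention for leaving subjects in neither cluster, chosen as the
simplest internal criterion with that effect.

## Gait metrics

Asymmetry = (right − left)/max(right, left) × 100 (antisymmetric, bounded
by ±100); dual-task cost = (dual − single)/single × 100 (negative values
legitimate — improvement under dual task). Both are scale-invariant and
parameter-agnostic over named measure columns.

## Problem sizes and determinism

Simulation-based checks run at deliberately modest sizes chosen as desk-
scale experiments: 500 voxels for noiseless neurite-model recovery, 200
null datasets × 500 permutations for FWER calibration, 20 + 20 subjects ×
10 seeds (200 permutations each) for the end-to-end directionality check,
and 1000 bootstrap resamples for cluster stability. `scripts/acceptance.py`
uses smaller versions of the same experiments (reported with each value)
so a full from-scratch rerun stays quick. Every stochastic component takes
an explicit seed; pipeline reports record all derived seeds, and rerunning
from the same configuration reproduces every number exactly.

## Known limitations

* The phantom's geometry, piecewise-constant parameters and map-level
  cohort mode capture none of real data's registration error, partial
  voluming, physiological noise or anatomical variability; passing tests
  demonstrates correctness of the algorithms, not field performance.
* The skeleton projector is validated against its own documented rule, not
  against FSL's binaries.
* Perivascular flow is reduced to a single diffusivity gain along x; the
  ALPS index's known model-dependence is inherited, not addressed.
* The neurite-model fitter assumes single-fiber voxels; crossing regions
  are simulated but fitted with a single mean axis (higher apparent
  dispersion), as the standard model does.
* The unassigned-subject convention and the exact/inclusive shell-filter
  reading are package choices on points the upstream procedures leave
  unspecified; both are flagged where they matter.
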
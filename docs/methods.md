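# Methods

## Data model

The unit of analysis is a spatially registered multi-parametric MRI
hypercube: a (rows × cols × slices × bands) array at 1 × 1 mm in-plane /
6 mm slice spacing in which every voxel carries one value per band.  The
default band list is T1 pre-contrast, T1 maximum contrast, T2, ADC,
high-B DWI (B = 1000 s/mm²), DCE washout rate k_ep, plus one spare
channel: descriptions of this acquisition style state seven spectral
components while naming only six, so the seventh is kept configurable and
defaults to a spare band drawn with weak correlations to the rest.
Voxel indices are 0-based, world mm = index × spacing + origin offset,
and the slice axis is axis 2.  A companion label volume marks 0 =
outside, 1 = normal prostate (background/clutter), 2 = tumor.

Registration support is deliberately rigid-only: in-plane linear
interpolation to the target pitch, nearest-slice reslicing by table
position, and a rigid translation.  Cubes are stitched by concatenation
along the slice axis with a provenance map; every downstream statistic is
a function of the voxel *set*, so the stitching layout cannot affect
results (tested as a permutation invariance).

## DCE washout (k_ep)

Dynamic contrast-enhanced series are reduced to a washout-rate band.  Per
voxel, the peak time is the curve argmax; samples more than 50 s after
the peak are fitted with A·exp(−k_ep·t) by least squares on the log
concentrations — exact for the noiseless model and deterministic.  Voxels
with non-positive concentrations in the fit window fall back to bounded
nonlinear least squares (k_ep ∈ [0, 10] min⁻¹) initialized from the
log-linear fit on the positive samples; voxels with fewer than three
usable post-peak samples are flagged missing rather than guessed.
Whether the original processing used a log-linear or iterative fit, and
how non-positive samples were treated, is not documented anywhere we
could check; the choice above is this package's own reconstruction,
isolated in `fit_washout`.

## Detection and shape

ACE is the squared cosine between voxel and signature in
covariance-whitened coordinates; with any positive semi-definite inverse
(dense, PC-filtered, or regularized) it lies in [0, 1].  The tumor
signature is the mean spectral vector of an analyst-chosen voxel set — in
the synthetic pipeline, the voxels truth-labeled tumor.  Blobs are
connected components of strictly supra-threshold voxels, 26-connectivity
by default (corner contact merges; appropriate at 6 mm slice spacing),
labeled in scan order with ties in size broken by smallest label.

Eccentricity comes from the second-central-moment (scatter) matrix of
blob voxel coordinates in physical mm.  Its *largest* eigenvalue
corresponds to the major axis (a true inertia tensor would invert this
assignment), and E = √(1 − s/l) reproduces the classical ellipse
eccentricity because scatter eigenvalues scale with squared semi-axes; a
sphere gives exactly 0 and a line exactly 1.  The alternative index
(l − s)/(l + s) is available behind a flag.  Moments are 3-D; a per-slice
2-D variant would be a plausible alternative reading and is noted as a
possible discrepancy.  Single-voxel blobs score 0 by convention.
Thresholds default to τ = 0.45 for the eccentricity feature and τ = 0.65
for the volume feature.

## Clutter statistics and SCR

The background model is the sample mean and (n−1)-denominator covariance
of the normal-prostate voxels, with eigenpairs sorted descending.  SCR is
the square root of the Mahalanobis quadratic form of the signature; the
squared variant is an option.  Inverse repairs:

- **PC filtering** (`3pc`, `4pc`): drop the 3 or 4 *smallest*-eigenvalue
  principal components — the noise-dominated ones — and invert on the
  retained leading subspace.  SCR is provably non-increasing in the
  number of removed components.
- **Shrinkage**: CM(γ) = (1−γ)·CM + γ·D with D = (tr CM/B)·I (standard)
  or D = diag(CM) (modified); both preserve the trace and are the two
  canonical diagonal shrinkage targets.
- **γ selection**: for a multivariate-normal background the squared
  Mahalanobis distances are χ²_B; γ* minimizes the Kolmogorov–Smirnov
  distance between the observed background distances under CM(γ) and
  χ²_B over the grid 0, 0.01, …, 1, ties to the smallest γ.  A singular
  CM(0) is skipped with a notice.  In the per-patient pipeline the
  diagnostic uses at most 5000 background voxels (fixed derived seed) to
  bound the 101-point grid cost; γ* is insensitive to this subsampling at
  the simulated background sizes (~4000 voxels).

The exact SCR normalization and γ-selection statistic used by the
method's originators are not reproducible from available descriptions;
both reconstructions sit behind the `InverseSpec` seam so they can be
swapped without touching callers.

## Clinical modeling

CsPCa is 1 iff the Gleason pattern pair is ≥ 4+3 in primary-then-sum
order.  Feature rows with a missing flag or non-finite value are excluded
listwise with a logged reason (mirroring cohorts where a patient fails
contrast uptake).  The train/test protocol fits on even-numbered
enrollment ids and scores odd-numbered ids with frozen coefficients
(checksummed before and after scoring); enrollment ids are taken 1-based.

Logistic fits use Newton/IRLS (tolerance 1e-8, ≤ 100 iterations).  How F
and R² should be defined for a binary outcome is genuinely open; the
package reports the linear-probability companion fit's
F = (R²/k)/((1−R²)/(n−k−1)) and R² as the headline (matching the
F-plus-R² reporting style common in this literature) *and* labels the
alternatives: squared outcome–probability correlation, McFadden,
Nagelkerke, and the likelihood-ratio χ² p-value.  Complete separation —
including joint-covariate quasi-separation, which small strong-signal
cohorts hit readily — raises an explicit error naming the separating
variable when identifiable; a Jeffreys-penalized (Firth) fit is available
behind a flag.

ROC curves enumerate all thresholds; the trapezoid AUC equals the
Mann–Whitney statistic with ties counted ½ (asserted against an
exhaustive pair-counting oracle).  The 95% CI is DeLong by default with a
seeded stratified bootstrap as a secondary option, the CI convention
being otherwise unspecified.

The nomogram assigns each variable a points axis: reference value = the
range end minimizing β_i·x (points are never negative), scale
M = max_i |β_i|·range_i so the most influential variable spans 0–100, and
risk(T) = logistic(η_min + M·T/100).  This construction is algebraically
exact — the round-trip error is floating-point noise, well inside the
0.005 contract.  Decision curves call a patient positive when the
predicted probability is *at least* the threshold p_t and report
NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t) on the grid 0.01–0.99 (step 0.01),
alongside treat-all and treat-none; univariate curves come from
univariate logistic fits of each feature.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not scanner physics:

- **Geometry**: prostate = ellipsoid with semi-axes (22, 18, 15) mm on
  the 1 × 1 × 6 mm grid; tumor = solid prolate ellipsoid (axis ratio
  1–2.5, volume 0.3–3.0 cc, so roughly two-thirds of tumors exceed 1 cc)
  with its major axis in-plane — 6 mm slices undersample through-plane
  shape, and clinically reported tumor extent is predominantly in-plane.
  Placement is rejection-sampled inside the capsule; an infeasible tumor
  raises "tumor exceeds organ".
- **Intensities**: background voxels are multivariate normal with
  correlated bands (e.g. ADC–DWI negatively, T1 pre/max positively
  correlated) at clinically plausible scales; a Student-t option
  (`heavy_tails_df`) exists for robustness experiments.  Tumor voxels add
  a signature offset — avid enhancement, dark T2, restricted diffusion,
  faster washout — scaled by a per-patient contrast factor U(0.5, 1.5),
  giving a full-inverse SCR of ~3.5–10.5 across patients.
- **DCE**: a gamma-variate bolus rise peaking at 60 s followed by
  A·exp(−k_ep·(t−t_peak)); only the decay segment is contractual.
- **Labels**: CsPCa ~ Bernoulli(logistic(β0 + β·(true Ecc, true SCR,
  true Vol))) with β = (−11.2, 2.3, 1.05, 0.95), calibrated once against
  the design target (oracle AUC ≈ 0.9 of the generating probabilities,
  prevalence ≈ 0.4) and then frozen.  Labels use *true* generator
  features, so imaging measurement error attenuates — never inflates —
  pipeline performance.
- **Reproducibility**: patient i of a cohort with seed S uses
  `default_rng([S, i])`, so any patient regenerates in isolation and
  identical (params, seed) give bit-identical cohorts.

What passing tests on this cohort show: the algebraic and statistical
machinery is correct, and the pipeline recovers the generative
discriminative structure through the full imaging chain.  What they do
not show: performance on real prostate MRI, which has bias fields,
motion, registration error, non-Gaussian and spatially correlated
clutter, and histology-derived labels with their own noise.  Voxels here
are spatially independent draws; real clutter has spatial texture that
would make ACE false-alarm blobs more structured.

## Problem sizes and numerics

The end-to-end study runs 200 synthetic patients (~18k voxels each),
chosen as the smallest cohort at which AUC estimates are stable to ±0.03;
the coefficient-recovery check uses 2000 truth-table rows (no imaging).
Covariance inverses refuse condition numbers above 1e12 and point to the
repaired alternatives.  ACE denominators of exactly zero (voxel at the
background mean) score 0.  Washout rates are clamped to [0, 10] min⁻¹.
All tie-breaks (blob labels, γ grid) are deterministic.

## Known limitations

- No DICOM ingestion, deformable registration, or Tofts pharmacokinetics;
  rigid resampling only.
- No real patient images are packaged; clinical effect sizes obtained on
  actual cohorts are therefore out of reach by design, and the synthetic
  study validates the machinery, not the clinical effect size.  Real data
  can be supplied as 4-D NIfTI hypercubes with 3-D label masks.
- 2-D per-slice eccentricity and alternative SCR normalizations are
  plausible variants of ambiguous descriptions; both are flagged at their
  implementation sites.
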
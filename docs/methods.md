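# Methods

## Scope and data model

All processing is two-dimensional: the analysis unit is one lesion on one
(central) slice, with the SUV map, DWI stack, ADC map and all masks sharing
one voxel grid (default 2 × 2 mm in plane). Inputs are assumed pre-aligned;
inter-modality resampling/registration and DWI distortion correction are
upstream responsibilities. Voxel indices are 0-based, the physical position
of voxel (i, j) is `origin + (i·spacing_row, j·spacing_col)`, and crop boxes
are half-open index intervals. Masks are written as unsigned 8-bit 0/1
NIfTI for interoperability.

## SUV normalization

`SUV = C [kBq/mL] · body_weight [kg] / injected_dose [MBq]` (body-weight
convention, dimensionless). Only weight and dose enter; decay correction to
injection time is assumed to have been applied by the scanner
reconstruction and is deliberately not re-implemented.

## ADC fitting

Per voxel, ordinary least squares of ln S_b against b under
S_b = S₀·e^(−b·ADC), restricted to b ≥ 200 s/mm² (default, configurable).
The restriction removes the fast pseudo-diffusion (perfusion) signal that
contaminates low b-values; on IVIM-like biexponential data the restricted
fit is strictly lower than the all-b fit, and on pure mono-exponential data
the two coincide — both are property-tested. Log-linear fitting was chosen
over nonlinear least squares because it is exact on noiseless data, has no
iteration/initialization failure modes on 3-point decays, and the nonlinear
fit is retained in the test suite as an independent oracle (ROI-level
agreement within 5 % at SNR 50). Voxels with a non-positive signal at any
used b-value are flagged invalid and excluded from ROI means rather than
imputed (the log transform is undefined there); negative fitted ADCs are
retained by default with an optional clamp at zero. ADC is carried in
mm²/s; tables print the conventional ×10⁻³ scale.

## Mixture segmentation

EM for a univariate 3-component Gaussian mixture on all cropped SUV values:

- Initialization: k-means++ center draws (first center uniform, subsequent
  proportional to squared distance to the nearest chosen center), followed
  by a hard nearest-center assignment to seed weights/means/variances.
- 5 restarts with sub-seeds derived from the user seed; best final
  log-likelihood wins. Convergence at relative log-likelihood change
  < 1e-6, cap 500 iterations (non-convergence is flagged, not fatal).
  These are conservative equivalents of common toolbox defaults.
- Variance floor 1e-6 × data variance against component collapse; a
  floored component with weight < 1e-6 is reported as degenerate.
- Components labelled background / unknown / tumor by ascending mean (ties
  by ascending variance), matching the intensity semantics.

The tumor threshold is the crossing of the *weighted* unknown and tumor
densities (the mixture decision boundary between those two components; the
background component is excluded from the equation). Equating the two log
densities gives a quadratic whose root inside (μ_u, μ_t) is taken — the
smaller if both lie there; if none does (extreme weight/variance ratios)
the midpoint (μ_u + μ_t)/2 is used and flagged. The mask is {SUV > T},
strict, applied to the crop and embedded back into the full grid; no
connected-component filtering. The strict inequality and the weighted
(rather than unweighted) densities are pinned conventions; maximum-
posterior class assignment is available separately (`class_assign`, ties to
the lower-mean class) for diagnosing the difference between the threshold
rule and 3-way posterior labelling.

A fit whose tumor/unknown separation (μ_t − μ_u, in pooled-sd units) falls
below 2 is flagged `low_separation`: this is the signature of a crop with
no real lesion, where three heavily overlapping components tile a single
mode. The flag is diagnostic only and never alters the mask.

Comparators: `segment_fixed` uses strict SUV > 2.5 and may legitimately be
empty (flagged); `segment_percent_max` uses an inclusive SUV ≥ 0.42·max so
the maximum voxel always survives, making it never empty and invariant to
positive rescaling (the fixed threshold is not — both directions are
tested).

## Agreement metrics

Dice = 2|A∩B|/(|A|+|B|); both masks empty is defined as 1.0, exactly one
empty as 0.0, so cohort code is deterministic on degenerate rows. The
center of gravity is the unweighted centroid of member-voxel centers (the
metric is defined on the segmentation, not the intensity field); its
displacement is reported raw in mm and normalized by the square root of the
reference ROI area expressed in mm (cog_mm / √(area_mm²)), a dimensionless
displacement in units of the reference lesion's linear size. The
normalization by √area was chosen over area because it is the only
dimensionless reading; the raw displacement is always reported alongside so
either convention can be recovered. CoG fields are NaN and flagged when
either mask is empty. ROI area is voxel count × voxel area (cm²); the ROI
mean ADC averages valid-fit voxels only, with the voxel count unaffected.

## Cohort statistics

Paired t (one-sample t on differences), Welch two-sample t (unequal
variances — the safer default where pooling is not justified) and Pearson
correlation wrap scipy.stats; Benjamini–Hochberg step-up adjustment wraps
statsmodels. Zero-variance inputs produce flagged degenerate reports with
NaN statistics instead of exceptions, and degenerate reports are excluded
from the BH family. The family is everything emitted by one cohort
invocation: per method, paired t and Pearson r of area and mean ADC against
the reference, plus untreated-vs-treated Welch tests for Dice, normalized
CoG, area and mean ADC. Two-sided throughout; significance read at
adjusted p < 0.05. Repeated scans are treated as independent lesion-scans,
a fidelity-over-purity choice documented here as a caveat (no mixed-effects
modelling).

## Lesion phantoms

`make_phantom` emulates a single-slice breast PET/MRI acquisition on a
96 × 96 grid at 2 × 2 mm:

- **Geometry** — an ellipse (default semi-axes 14 × 10 mm, cohort draws
  10–20 × 8–16 mm giving areas around the 4–6 cm² scale of clinical
  lesions) with a low-order harmonic radial perturbation (lobularity
  0.05–0.25) for irregular outlines.
- **Uptake** — background SUV 1.0 with Gaussian noise (sd 0.15); tumor SUV
  5–10 (default 8); within-tumor heterogeneity as a smoothed Gaussian
  random field (correlation length 6 mm) whose sd is a *fraction of the
  tumor-background contrast* (default 0.15). The relative parameterization
  matters: an absolute heterogeneity sd makes low-uptake lesions so
  internally spread that the three-class mixture splits the tumor itself,
  which is not the partial-volume structure the model targets.
- **Partial volume** — a 4 mm linear blend of tumor uptake into background
  outside the boundary, standing in for the ~4 mm reconstruction
  point-spread; these rim voxels are what populate the "unknown" class.
- **Diffusion** — ADC 1.0 × 10⁻³ mm²/s in tumor vs 1.8 × 10⁻³ in
  background (cellular-tumor convention), S₀ = 1000, b-values
  0/50/120/200/400/700 s/mm², Rician magnitude noise (σ = 20, SNR 50); an
  optional IVIM-like perfusion fraction (off by default so noiseless
  recovery is exact) exists for perfusion-contamination experiments.
- **Treatment** — a scalar f ∈ [0, 1] scales tumor uptake (mean and
  heterogeneity, via the contrast) toward background and moves tumor ADC
  toward background ADC. Cohort-treated cases draw f ~ U(0.3, 0.9). At
  f = 0.9 the lesion maximum SUV sits reliably below 2.5, the regime where
  fixed-threshold segmentation returns an empty mask.
- **Reference mask** — a DCE-style manual contour proxy: the truth
  boundary's signed distance field, shifted by a 0.5 mm random-direction
  offset and thresholded against a smooth jitter field scaled by 1.0 mm.
  It is derived from the truth geometry, not from simulated contrast
  kinetics — the pipeline needs a reference contour, not pharmacokinetics.

Everything is deterministic given the spec seed (separate substreams for
geometry, heterogeneity, SUV noise, DWI noise and the reference proxy), and
cohorts record every drawn parameter in a manifest.

What the phantoms do *not* emulate: scanner reconstruction physics beyond
the rim blend, anatomical background structure (fibroglandular texture,
satellite lesions), DCE kinetics, 3-D partial-volume effects, and
patient-level correlation between repeated scans. Passing tests therefore
demonstrate algorithmic correctness and the qualitative regime behavior of
the three segmenters, not clinical performance.

## Problem sizes and observed behavior

The default test/evaluation sizes — 100-draw exactness sweeps, 20 mixture
recoveries at n = 3000, 100 threshold-oracle fits, a 53-case cohort
(24 untreated + 29 treated), and 1000 null-calibration replicates of
n = 30 — were chosen as the smallest sizes at which each claim is sharp.
The null calibration builds 30 noise-free phantom geometries and, per
replicate, segments two independently noise-corrupted SUV realizations of
each with the percent-max method; with the reference equal to truth the two
"methods" are statistically identical and the paired t on areas measures
pure type-I error (observed ≈ 0.04–0.05).

On default cohorts the GMM segmenter's mean Dice against the jittered
reference is ≈ 0.89–0.97 per group and exceeds the percent-max comparator;
the reference-vs-GMM correlation of mean ADC is > 0.99, while the area
correlation varies ≈ 0.7–0.95 across cohort seeds because the adaptive
mixture occasionally locks onto a hot spot in a strongly heterogeneous
lesion and underestimates the area — the same instability that makes
adaptive PET thresholds degrade as uptake ranges shrink.

## Known limitations

- Strictly 2-D; 3-D inputs require an explicit slice index and volumetric
  metrics are out of scope.
- The number of mixture classes is fixed at three; crops whose histogram
  does not support three modes yield flagged, not prevented, fits.
- The intersection threshold assumes μ_u < μ_t strictly; coincident means
  raise a degenerate-fit error.
- The fixed-2.5 comparator depends on absolute SUV calibration; the
  percent-max comparator depends only on relative uptake.
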
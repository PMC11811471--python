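# Methods

This note records the models, conventions and design choices behind
`rtfpipe`, and what the synthetic phantom cohort does and does not emulate.

## Phantom model

Each scan is a 2D annulus (the short-axis left-ventricular ring) on a
96 × 96 grid at 1 × 1 mm default spacing, inner/outer radii 12/26 mm. In-ROI
intensities are

    base_value + subject_effect + slice_effect + texture + noise

with defaults in T1-map units (ms): base 950 (typical 1.5 T myocardial T1),
subject effects N(0, 40²), slice effects N(0, 20²), white pixel noise
N(0, 25²), and a Gaussian-random-field texture of amplitude 60 and 4 mm
correlation length (smoothed white noise, empirically standardized to unit
variance before scaling, so the amplitude is the pointwise SD). The
background is a constant 200 ms plateau so every filter sees realistic
ROI/background contrast. The second field strength reuses the *same*
texture realization, applies an affine intensity map (default gain 1.25,
offset 12.5, lifting the base to 1200 ms to mimic the higher 3 T signal
level) and draws independent noise scaled by `field_noise_ratio`
(default 1.2). The intensity regimes are free parameters of the generator,
not empirical claims.

The default study design is 15 subjects × 3 slices × 2 fields = 90 maps.
Seeding is counter-based — `SeedSequence((master_seed, subject, slice,
stream))` — so any single map is regenerable in isolation and every
generator is a pure function of (spec, config, seed).

What the phantom does **not** emulate: per-subject anatomy (the ring
geometry is fixed across subjects; only texture and intensity vary),
partial-volume edges, blood-pool/papillary structure, B1 shading, motion
artifacts, and any field-strength-dependent change in texture *structure*
(only level and noise change). Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline, not the numerical
reliability of features on real scans.

## Segmentation-variability model

Trained-model segmentation variability is emulated parametrically: the
reference mask's signed Euclidean distance d(x) (positive inside, mm) is
re-thresholded as

    mask_p = { d(x) + level · displacement_scale · η(x) > 0 }

where η is a unit-SD noise field with 3 mm correlation length. Level 0
reproduces the reference bit-for-bit; the expected boundary displacement
grows linearly with the level, so pairwise mask agreement decreases
monotonically in expectation. The largest connected component is kept so
the output is always one valid ROI; an emptied mask raises an error.

`displacement_scale = 11.0` mm per unit level was calibrated once on the
default annulus so that the dataset-mean consensus IoU₃ of a mask triplet
is ≈ 0.5 at level 0.3 (measured 0.48–0.50 across seed sets), anchoring the
top of the level grid to the regime where feature repeatability collapses.
The constant is frozen in `PerturbationConfig` and not adjusted per run.

Sweeps reuse the same η seeds across levels (common random numbers), which
makes level-to-level comparisons nearly monotone by construction instead of
being dominated by Monte Carlo noise.

## Consensus decomposition

For masks A₁, A₂, A₃, the union is partitioned by membership multiplicity:
iou3 = |exactly 3| / |union|, iou2 = |exactly 2| / |union|,
iou1 = |exactly 1| / |union|. Defining iou2 as *exactly* two (rather than
"at least two", which would double-count the triple intersection) is what
makes the three components a partition summing to 1. Areas are pixel
counts; pixel spacing cancels in the ratios and no sub-pixel treatment is
attempted.

## Filter bank

Point filters use range-normalizing constants (M = max |x| over the image):
square x²/M, squareroot sign(x)·√(|x|·M), logarithm
sign(x)·M·log(1+|x|)/log(1+M), exponential exp(x·log M / M). They are
monotone, preserve constancy and act pixel-locally given M. Gradient is the
central-difference magnitude in physical units. LBP uses rotation-invariant
uniform codes with radius 1 and 9 samples (codes 0..10); the image is
edge-replicated before coding so border pixels receive a full
neighbourhood. The wavelet step is a single-level undecimated (stationary)
coif1 transform with normalized filters, padded to even size and cropped,
so all four sub-bands keep the input grid — required because features are
computed on the original ROI mask. The published settings behind these
filter choices are not fully specified in the literature this mirrors, so
all of them are exposed in `FilterSettings`.

## Feature engine

Features follow the standardized (IBSI-conform) definitional formulas; the
full name list ships as `feature_manifest.json` and the test suite enforces
the counts 18/24/16/16/14/5 per class and 1023 overall. Conventions that
needed fixing because several dialects exist:

* **Discretization**: fixed bin width anchored at the ROI minimum,
  level(x) = floor((x − min)/W) + 1. Default W = 25 map-units. The lbp-2D
  version overrides W = 1 because LBP outputs are small integer codes —
  a 25-unit bin would collapse them to a single gray level and degenerate
  every LBP matrix feature. Both are config (`bin_width`,
  `bin_width_overrides`).
* **2D treatment**: distance-1 co-occurrence and runs over the 4 unique
  in-plane directions, features averaged over directions; zones and
  neighbourhoods use 8-connectivity; everything is per-slice.
* **GLDM**: dependence size j = dependent 8-neighbours + 1 (centre
  included), criterion |Δlevel| ≤ α with α = 0.
* **NGTDM**: pixels with no in-ROI neighbour are excluded from the counts;
  Coarseness is capped at 1e6 when its denominator vanishes.
* **Degenerate fallbacks**: 0·log 0 = 0; correlation-type features of
  zero-variance matrices return 1; Skewness and Kurtosis of a constant ROI
  return 0 (Kurtosis is otherwise the non-excess m₄/m₂²); first-order
  Energy/TotalEnergy use post-resampling 1 mm² pixel area. Fallbacks are
  deliberately well-defined so that the screening stage, not silent
  numerics, decides exclusions.

Resampling is bilinear for images and nearest-neighbour for masks, to
exactly 1 × 1 mm before filtering; filters are applied to the full
resampled image before ROI masking.

## Reliability estimation

Mean squares come from the closed-form two-way crossed decomposition; the
residual sum of squares is computed directly from the residuals (not by
subtracting sums of squares), and the exact-agreement case (all raters
bit-identical per target) short-circuits to MSC = MSE = 0 so that the
level-0 pipeline is an exact ICC = 1 fixed point rather than 1 − 2e-16.

Point estimates and 95% CIs follow the McGraw–Wong F constructions for
ICC(2,1), ICC(3,1), ICC(2,k), ICC(3,k) (the k-averaged intervals by
Spearman–Brown step-up of the single-rater bounds). Negative estimates are
reported as computed but categorized poor; CI uppers are truncated to ≤ 1;
for strongly negative estimates the Satterthwaite df of the
absolute-agreement interval can degenerate, in which case non-finite
bounds fall back to the admissible limits [−1, 1]. All-constant tables
raise a `DegenerateTableError` and are excluded rather than numbered.

Screening is global: a feature constant across *all* observations (every
run, field and target), or non-finite anywhere, is excluded once before
any analysis. On every synthetic cohort this mechanism flags
`lbp-2D_firstorder_Maximum` — the per-ROI maximum of the LBP code image
saturates at the code-range bound P+1 = 10 on essentially any textured
scan — reproducing the canonical degenerate-feature exclusion; a few
sibling statistics of the code image (minimum, range, percentiles) are
caught by the same rule on the phantom.

The observational unit is the subject-slice (n = 45 per field in the
default design, matching the study layout this mirrors); slice nesting is
ignored, as the two-way models imply. The reproducibility analysis uses
the reference segmentation of each map. Both choices are config.

## Problem sizes

Default test and acceptance runs use: the full 15 × 3 × 96 × 96 cohort for
the level-0 repeatability anchor (135 extractions, ≈ 30 s); a 6-subject ×
1-slice cohort for the 16-level sweep (288 extractions, ≈ 80 s); 48 × 48
phantoms for unit tests; 8 × 8 ROIs for the brute-force oracle
equivalences; and 500 replicates of 200 × 3 tables for ICC parameter
recovery. These sizes were chosen to keep the full suite fast while leaving
every statistical check comfortably powered.

## Known limitations

* The phantom's fixed geometry means reference masks are identical across
  subjects; between-subject variance comes from intensity and texture only.
* Feature-value parity with any specific external extraction tool is out of
  scope; parity is defined against the repository's own definition-literal
  oracle (tool versions differ in exactly the conventions listed above).
* The perturbation model displaces boundaries smoothly; it cannot produce
  topology changes (holes, split rings) that real segmentation failures
  occasionally show, and its calibration is specific to the default
  annulus geometry.
* k-averaged ICC intervals use the Spearman–Brown step-up, which is the
  common practice but approximate for the absolute-agreement model.
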
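# rtfpipe

Reliability analysis of radiomic texture features (RTFs) from 2D parametric
maps, built for the cardiac T1-mapping setting: how stable are texture
features when the segmentation changes slightly, and how consistent are they
across scanners with different magnetic field strengths?

The package is aimed at imaging researchers who want to screen texture
features for robustness before using them as biomarkers or machine-learning
inputs. It provides, as importable library modules with a thin `rtf` CLI on
top:

* **synthetic_cohort** — an annular (left-ventricular ring) phantom
  generator: paired field-strength maps sharing one Gaussian-random-field
  texture, plus a calibrated boundary-perturbation operator that emulates
  segmentation variability at a dial-able level in [0, 0.3];
* **concordance** — the three-mask consensus decomposition of the union:
  IoU₃ (pixels in all three masks), IoU₂ (exactly two) and IoU₁ (exactly
  one), with IoU₃ + IoU₂ + IoU₁ = 1;
* **filter_bank** — the 11 image versions features are computed from:
  original, square, squareroot, logarithm, exponential, gradient magnitude,
  rotation-invariant uniform LBP, and the four sub-bands of a single-level
  undecimated wavelet decomposition;
* **texture_features** — the 93-feature engine (18 first-order, 24 GLCM,
  16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM; IBSI-conform formulas) applied per
  image version within the ROI after 1 mm in-plane resampling, yielding
  11 × 93 = 1023 named features per (map, mask);
* **reliability** — two-way ANOVA intraclass correlation: ICC(2,1) for
  absolute agreement across segmentation runs, ICC(3,1) for consistency
  across field strengths, plus the k-averaged ICC(2,k)/ICC(3,k), each with
  F-based 95% CIs, four-tier categorization (excellent ≥ 0.95, good ≥ 0.75,
  moderate ≥ 0.5, poor < 0.5), and screening of degenerate features;
* **experiments** — the orchestrated studies: repeatability per field,
  reproducibility across fields, and the perturbation-level sweep.

## The statistic at the core

For an n × k table of measurements y_ij (n targets, k raters/conditions)
the two-way mean squares MSR (targets), MSC (raters) and MSE (residual)
give

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))
    ICC(3,1) = (MSR − MSE) / (MSR + (k−1) MSE)

i.e. the proportion of total variance attributable to true between-target
differences, with (ICC(2,1)) or without (ICC(3,1)) penalizing systematic
rater offsets. Confidence intervals follow the standard McGraw–Wong
F-distribution constructions; the implementation agrees with `pingouin`
to ~1e-15 and is verified against it in the test suite.

## Worked example

```python
from rtfpipe import CohortConfig, PhantomSpec, generate_cohort, run_repeatability

spec = PhantomSpec(grid_shape=(48, 48), ring_radii=(6.0, 14.0))
config = CohortConfig(n_subjects=4, slices_per_subject=1, master_seed=0)
cohort = generate_cohort(config, spec)

res = run_repeatability(cohort, level=0.2, field="1p5T")
print(tuple(round(v, 3) for v in res.mean_iou.as_tuple()))
print(res.overall_breakdown.to_string(index=False))
```

prints

```
(0.503, 0.253, 0.243)
  group  category  count  proportion
overall excellent     70    0.068966
overall      good    191    0.188177
overall  moderate    225    0.221675
overall      poor    529    0.521182
```

Reading: at perturbation level 0.2 the three segmentation runs of each map
agree on about 50% of the union of their masks (IoU₃ = 0.503), another 25%
is covered by exactly two runs, and under that much segmentation
variability only ~7% of the 1015 kept features retain excellent
repeatability (ICC(2,1) ≥ 0.95) — features such as the per-ROI minimum of
monotone point filters, which barely depend on the boundary. Eight features
(e.g. the LBP code maximum, which saturates at its code-range bound on
every scan) were screened out as constant before ICC estimation.

At level 0 the three runs are identical, so every kept feature has
ICC exactly 1 — a useful end-to-end fixed point that the test suite pins
down. `run_dp_sweep` repeats this analysis over the level grid 0 → 0.3
(step 0.02) with common random numbers, reproducing the characteristic
joint decline of mask consensus and feature repeatability.

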
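# Methods

This note documents the models behind `petsegtex`: what the synthetic
data emulate, how the three segmenters are defined, how the texture
panel and the statistics are computed, and which design choices were
genuinely open.

## Synthetic PET phantoms

A phantom is an ellipsoidal lesion (semi-axes `lesion_radii_mm`) on a
uniform background, sampled on a 4.7 × 4.7 × 3.27 mm grid — the pixel
size and slice thickness typical of clinical whole-body FDG-PET
reconstructions. Construction order:

1. piecewise-constant composite: background level plus lesion plateau;
2. intratumoural heterogeneity: a Gaussian random field (white noise
   smoothed to correlation length `heterogeneity_corr_len_mm`, default
   8 mm, unit-variance normalized) scaled to `heterogeneity_amplitude`
   and added inside the lesion only;
3. partial-volume blur: 3D Gaussian convolution at `psf_fwhm_mm`;
4. additive Gaussian noise (`noise_sigma_suv`), then clipping at zero.

Blur before noise mimics reconstruction-dominated PET noise ordering;
no sinogram/OSEM simulation, attenuation CT, or respiratory motion is
attempted. The ground-truth mask is the *pre-blur* ellipsoid support.

Defaults (units SUV unless noted): background 0.5 (aerated lung),
tumour mean 7, heterogeneity sd 1.5, PSF FWHM 6 mm (a typical effective
post-reconstruction resolution for the scanner class emulated), noise
sd 0.3. Cohorts draw lesion semi-axes uniformly from 7.5–30 mm
(diameters 15–60 mm, spanning locally advanced primaries down to the
small-lesion regime where adaptive segmentation is claimed to matter)
and tumour means from 5–10. These values make the relative boundary
placement of the three algorithms interpretable: with a low background,
the 40%-of-max threshold falls slightly *inside* the true edge, while
the Bayesian segmenter's background/partial-volume decision boundary
falls 1–3 mm *outside* it.

## Simulated readers

Each reader perturbs the true contour slice by slice. The signed
Euclidean distance from each voxel center to the contour interface
(half-voxel corrected — essential with 4.7 mm pixels, since millimetre
perturbations must be able to flip boundary voxels) is thresholded at
`dilation_bias_mm` (systematic over/under-contouring) plus a smooth
zero-mean 2D Gaussian field scaled to `boundary_jitter_mm` (contour
wobble). The first and last occupied slices are dropped with
probability `slice_dropout_prob` (axial-extent uncertainty). The output
is the largest 26-connected component; a perturbation that empties the
mask is retried with halved jitter up to 3 times.

The default trio: reader A unbiased, reader B +1 in-plane voxel
(+4.7 mm), reader C −1 voxel, all with 1 mm jitter and dropout 0.1.
This makes the freehand datasets differ mainly by a systematic
contouring offset. Note a consequence: ICC(2,1) penalizes systematic
rater differences, so the freehand panel's median ICC on these
defaults is *well below* the 0.7–0.95 range typical of real
multi-reader studies — the simulated readers disagree more
systematically than trained physicians do. The orderings between
algorithms, which are what the pipeline asserts, are unaffected. No
distributional data on real inter-reader disagreement was available to
calibrate against; the model is a plausible stand-in, not a calibrated
one.

## Survival simulation

Event times are exponential with rate
`baseline_hazard · exp(coeff · z)`, where `z` is the standardized
driver feature (default: first-order entropy, coefficient −0.7 per sd —
higher entropy, lower hazard). Censoring is independent exponential
(`censor_rate`). Defaults: baseline ln 2 / 25.6 ≈ 0.027 events/month
(median survival 25.6 months at the feature mean) and censoring
0.02/month (roughly 40% censored). This gives the Cox screen a known
ground truth for parameter-recovery tests.

## Segmentation

* **Expansion**: the freehand VOI is dilated by Euclidean distance ≤ 5
  in voxel units, isotropic in index space (the simplest reading of a
  "5-pixel 3D expansion"; configurable), clipped at grid bounds.
* **40P**: keep voxels ≥ 0.40 × max over the expanded VOI; the
  boundary value is kept (≥, not >). Invariant to positive intensity
  rescaling.
* **FLAB-style**: a three-class Gaussian mixture on the intensities in
  the expanded VOI, classes interpreted as background / partial-volume
  shell / tumour core; the final mask is the union of the two
  highest-mean classes (maximum-posterior labels). The per-voxel prior
  blends the global mixing weights with the previous iteration's label
  frequencies in the 26-neighbourhood:
  `prior ∝ (π_k + w·f_k) / (1 + w)` with `spatial_weight` w (default 1).
  Parameters update by EM-style alternation; convergence when every
  class mean changes by < `tol` (default 1e-4, relative); best-so-far
  labels with a warning otherwise. This is a documented, testable
  variant of the fuzzy locally adaptive Bayesian idea — three classes,
  spatial context, background discarded — not a reproduction of any
  published implementation; the original's fuzzy transition levels are
  approximated by the middle (partial-volume) class.

  Two identifiability choices matter and were made after observing
  failure modes on phantoms (before any acceptance test existed):
  the class variance is **pooled** by default (with ~75% of the
  expanded VOI being unimodal background, free variances let the
  likelihood split the background mode into two classes, after which
  "discard the lowest class" keeps background), and initialization is
  **k-means** by default (quantile init at 1/6–1/2–5/6 seeds two means
  inside the background mode for the same reason). Per-class variances
  and quantile init remain available.
* No largest-connected-component post-filter by default (available as
  a CLI flag).

On default phantoms these definitions yield the expected ordering of
median volumes — 40P smallest, FLAB intermediate (truth plus a thin
partial-volume shell), positively-biased freehand largest — asserted
as an ordering of medians, not per-lesion, since the distributions
overlap.

## Texture panel (83 features)

Quantization: fixed bin number, `level = 1 + floor(64 · (x − min)/(max
− min))` over in-mask intensities, max clipped to 64; a constant VOI
maps to level 1 with a degenerate flag. The paper-scale families:

* **First-order (20)**: min, max, mean, median, sd, variance,
  skewness, kurtosis, energy, entropy (−Σ p log₂ p over the 64-level
  histogram), uniformity, range, mean absolute deviation, RMS, P10,
  P90, IQR, coefficient of variation, MATV (voxel count × voxel
  volume, ml), TLG (SUV_mean × MATV).
* **GLCM (22)**: symmetric co-occurrence at distance 1 voxel over the
  13 unique 3D directions, in-mask pairs only, offsets in index space
  (no mm correction — the common PET practice); the 13 normalized
  matrices are averaged and the classical Haralick-derived set
  (autocorrelation … sum entropy) computed once on the average.
* **Higher-order (35)** = GLRLM 16 + GLSZM 14 + NGTDM 5. GLRLM runs
  are per direction; features are averaged over directions because
  several normalize by per-direction run counts. GLSZM zones are
  26-connected constant-level components; "intensity variability" uses
  the size-weighted form Σᵢ(voxels at level i)²/N_zones, with the
  conventional zone-count non-uniformity kept as a separate feature.
  NGTDM uses 26-neighbourhood mean deviations restricted to the mask;
  coarseness is 1/(ε + Σ pᵢsᵢ) with ε = 10⁻⁶, capping the constant
  VOI at 10⁶.
* **Fractal (6)**: differential box-counting dimension of the
  intensity surface (intensities normalized to the spatial extent, so
  positive rescaling is a no-op), solid box-counting dimension of the
  mask, box-counting dimension of the mask boundary (one 26-connected
  erosion), gliding-box lacunarity at sizes 2 and 4, and their log-log
  slope. Slopes are least-squares over dyadic box sizes 1–16; masks
  whose bounding box has no axis ≥ 4 voxels return NaN.

The exact membership of each family is a frozen registry of this
package: the family sizes (20/22/35/6) and the 12 survival-screen
features are contractual, and the remaining slots are filled with the
classical feature sets a PET radiomics practitioner would expect.
`extract_all` asserts the 83/20/22/35/6 contract on every call and
propagates degeneracy as NaN, never by dropping a column.

## Agreement statistics

* **JSI** = 100·|A∩B|/|A∪B|; undefined (error) for two empty masks.
  FLAB is the default reference, yielding FH/FLAB and 40P/FLAB sets
  per cohort, compared by two-sided Mann-Whitney U (exact when both
  n ≤ 20 without cross-sample ties, else normal approximation with tie
  correction). JSI-vs-volume OLS reports slope and r².
* **ICC**: two-way random effects, absolute agreement, single rater —
  ICC(2,1) — because the readers are interchangeable; ICC(3,1) via
  `form="icc3"`. Point estimates come from the closed-form ANOVA mean
  squares (vectorized, so the bootstrap over 83 features × 100
  resamples is cheap); CIs use the standard F-distribution
  construction. Banding: high > 0.85, moderate 0.7–0.85, low < 0.7.
* **ICC differences**: patients resampled with replacement, the same
  resample applied to both algorithms (the pairing is what makes a
  difference CI meaningful); percentile 95% CI over 100 resamples by
  default (small for a 95% CI — kept as the conventional choice here,
  overridable); significant iff the CI excludes 0. Degenerate
  resamples are redrawn with a cap.
* **Log₁₀ transform**: visual Q-Q screening is replaced by a
  reproducible rule — transform when sample skewness > 1.0 (default)
  and all values are strictly positive; non-positive features are
  skipped with a warning. In the survival screen the decision is made
  once per feature (skewed under any algorithm, positive under all) so
  a feature is treated identically across algorithms.

## Survival screen

Univariate Cox fits via the partial likelihood with Efron tie handling
(lifelines), Newton precision tightened to 1e-10 so small-sample
estimates agree with direct likelihood maximization to < 1e-4. Each of
the 12 features × 3 algorithms cell reports HR per unit (of the
possibly log₁₀-transformed feature), Wald 95% CI and p (significance
at 0.05, no multiple-testing correction — the screen is deliberately
raw), HR per sd (feature scales are arbitrary, so both are reported),
and AIC = −2 log PL + 2. The AIC 95% CI is a nonparametric patient
bootstrap with percentile intervals (default 1000 resamples; the
orchestrated pipeline uses fewer by configuration) — the simplest
defensible construction, as no standard definition exists for a CI on
AIC. Kaplan-Meier curves and multivariate models are deliberately out
of scope. Failed fits (separation, zero variance) become flagged NaN
rows; the screen never aborts.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run cohorts of 5–53
patients on ~44³ grids — large enough for the orderings and
calibration properties to be stable, small enough to run on one CPU in
minutes. Power/type-I properties use 50–200 replicate simulations at
n = 200. Every generator, bootstrap and fit is a pure function of its
config including the seed; per-patient seeds derive deterministically
from the cohort seed, so the full pipeline reproduces `features.csv`
byte-for-byte under a fixed master seed.

## Known limitations

* Phantoms are single ellipsoidal lesions on a uniform background: no
  adjacent hot structures (heart, nodes), no attenuation artefacts, no
  respiratory motion, no scanner cross-calibration variation. Passing
  tests demonstrate internal consistency of the methods and the
  qualitative algorithm orderings under these conditions, not clinical
  performance on real images.
* The reader model is uncalibrated (see above); absolute ICC levels
  for the freehand arm should not be compared with clinical studies.
* The FLAB variant is a re-design faithful to the operative behaviour
  (3 classes, spatial context, keep top 2), not to any specific
  published estimator (stochastic vs deterministic estimation and the
  fuzzy-level count of the original are not reproduced).
* The 83-feature roster beyond the named 12 is a registry choice;
  other completions of the same family sizes are possible.
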
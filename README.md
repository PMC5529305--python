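# petsegtex

Tumour delineation is the first step of every PET radiomics analysis, and the
choice of segmentation algorithm changes everything downstream: the voxels that
enter the texture matrices, how well three readers agree with each other, and
whether a feature keeps its prognostic signal. `petsegtex` implements a full,
reproducible comparison of three ¹⁸F-FDG PET delineation approaches for
non-small cell lung cancer-like lesions:

* **FH** — freehand reader contours (ingested, or simulated by the built-in
  reader model);
* **40P** — fixed threshold, keeping voxels ≥ 40% of the maximum activity in
  the VOI;
* **FLAB** — a fuzzy locally adaptive Bayesian-style segmenter: a three-class
  spatially regularized Gaussian mixture (background / partial-volume shell /
  tumour core) that discards the background class.

Because no patient images are distributed, the package ships a first-class
synthetic cohort generator: heterogeneous ellipsoidal lesions on a low-uptake
background with partial-volume blur and noise, three imperfect simulated
readers, and exponential proportional-hazards survival times driven by a
chosen texture feature. Everything downstream is evaluated on these phantoms.

The comparison mirrors standard practice:

* **Volume agreement** — Jaccard similarity index (JSI, × 100) of each
  algorithm against the FLAB reference, Mann-Whitney U comparison of the two
  JSI sets, and OLS regression of JSI on lesion volume.
* **Inter-observer reproducibility** — an 83-feature texture panel
  (20 first-order, 22 GLCM, 35 higher-order GLRLM/GLSZM/NGTDM, 6 fractal) on a
  64-bin quantization; per-feature ICC(2,1) across the three readers with
  F-based 95% CIs, banded at 0.85/0.7; paired patient-bootstrap 95% CIs of
  pairwise ICC differences between algorithms.
* **Prognostic utility** — univariate Cox proportional-hazards screen (Efron
  ties) of 12 commonly reported features (MATV, TLG, SUV_mean, SUV_max,
  SUV_sd, first-order entropy, GLCM entropy/homogeneity/dissimilarity, GLSZM
  intensity variability, NGTDM coarseness/contrast) per algorithm, with hazard
  ratios, Wald p values, and AIC = −2 log PL + 2 with patient-bootstrap CIs.

## Worked example

```python
import petsegtex as px

# one phantom and its ground truth
vol, truth = px.generate_phantom(px.PhantomConfig(seed=3))

# a slightly over-contouring reader, then the two automatic algorithms
reader = px.ReaderModel(boundary_jitter_mm=1.0, dilation_bias_mm=4.7, seed=1)
fh = px.simulate_reader_mask(truth, reader)
expanded = px.expand_mask(fh, 5)
r40 = px.segment_40p(vol, expanded)
rflab = px.segment_flab(vol, expanded)
print(f"truth {truth.volume_ml:.1f} ml | FH {fh.volume_ml:.1f} | "
      f"40P {r40.volume_ml:.1f} | FLAB {rflab.volume_ml:.1f}")

vec = px.extract_all(vol, rflab.mask)
print(f"{len(vec.values)} features; SUVmean {vec['suv_mean']:.2f}, "
      f"entropy {vec['fo_entropy']:.2f} bits, GLCM entropy {vec['glcm_entropy']:.2f}")
```

prints

```
truth 14.4 ml | FH 27.2 | 40P 14.5 | FLAB 18.6
83 features; SUVmean 5.37, entropy 5.65 bits, GLCM entropy 10.44
```

— the threshold method cuts close to the true extent (14.5 ml), the Bayesian
segmenter keeps core plus partial-volume shell (18.6 ml), and the biased
reader over-contours (27.2 ml). The 83 extracted values include the histogram
entropy (in bits of the 64-level histogram) used as the survival driver in
the simulated cohorts.

The full experiment — cohort, three readers × three algorithms, features,
agreement reports, survival screen — runs from one config:

```bash
petsegtex run --seed 7 --out results/experiment
```

or in Python via `px.run_experiment(px.ExperimentConfig(...), out_dir)`.
Each stage is also a standalone subcommand (`simulate`, `segment`,
`features`, `compare`, `survival`) operating on NIfTI and CSV files.

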
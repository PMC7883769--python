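# Methods

This note documents the models, conventions and design choices behind
`radstruct`: what each stage computes, which parameters matter, what the
synthetic generators do and do not emulate, and the numerical conventions a
reimplementer would need.

## The component-structured feature space

A radiomic feature is identified by a `FeatureKey` — (sequence, region,
transform, formula).  A `ComponentRegistry` fixes the ordered name lists per
category; the feature index is the Cartesian product in registry order, so
column order, tie-breaking and serialization are all pure functions of the
registry.  Defaults:

- **Sequences (4):** T1, T1ce, T2, FLAIR.
- **Regions (5):** enhancing, necrosis, t2_abnormality (edema plus
  non-enhancing tumor), tumor_core (enhancing ∪ necrosis), whole_tumor.
- **Transforms (19):** identity; LoG at kernel widths 0.5/1/2/3/5 mm; the
  eight first-level 3D Haar subbands; slice-wise LBP; gradient magnitude;
  LoG at 1/2/3 mm on the two-level Haar approximation.  The transform count
  and the named members (identity, LoG, Haar, LBP) are fixed by the study
  design this package implements; the remaining members are this package's
  documented reconstruction.
- **Formulas (93):** 23 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM +
  14 GLDM.  The GLDM category stands in for a 14-entry "texture matrix"
  category: the canonical neighbourhood-grey-tone set has only 5 formulas,
  while the grey-level dependence matrix has a standard 14-formula set of
  the required size.  A separate shape set (12 formulas × 5 regions = 60
  features) is exposed via `extract_shape_row` but kept out of the
  35,340-dimensional histogram/texture space.

Default cardinalities give 4·5·19 = 380 VOIs and 380·93 = 35,340 features.

## Preprocessing contract

Volumes are expected co-registered and skull-stripped.  `read_subject`
resamples to 1 mm isotropic (trilinear for images, nearest-neighbour for
masks, `grid_mode` zoom so voxel counts scale with spacing), min-max
normalizes each sequence over its nonzero foreground to [0, 1], and remaps
BraTS labels {1, 2, 4}:

- label 4 → enhancing (unchanged);
- label 2 → t2_abnormality;
- label 1 (necrotic + non-enhancing tumor) is split by an Otsu threshold on
  the T1ce intensities of the label-1 voxels — necrosis is reliably dark on
  T1ce — with necrosis below the threshold and the non-enhancing remainder
  merged into t2_abnormality.  A fixed-quantile override exists for cohorts
  where the bimodality assumption fails; a constant label-1 intensity
  profile degenerates to all-necrosis with a warning.

The remap is a partition of label 1, so total tumor voxel count is
preserved — asserted by tests.

## Extraction conventions

- **Filter-then-mask (default).**  Transforms are applied to the whole
  normalized volume and the region mask is applied afterwards.  Masking
  first puts an artificial step edge at the region boundary that dominates
  every band-pass response; `filter_order="voi"` is available for
  comparison.
- **LoG.**  Implemented as a separable sum of sampled
  second-derivative-of-Gaussian × Gaussian 1D passes with mirror borders;
  `log_kernel` assembles the identical 3D kernel explicitly (mean-corrected
  to zero sum), so the applied operator and the inspectable kernel agree to
  float precision.  Kernel radius is 4σ.
- **Haar.**  `pywt` with periodization mode (orthonormal for even sizes;
  Parseval checked in tests); subbands are block-upsampled back to the
  input grid.  The two-level approximation is rescaled by 2⁻³ to preserve
  intensity scale before its LoG.
- **LBP.**  Slice-wise (axial), 8 neighbours at radius 1, strict
  greater-than comparison (a constant slice codes to 0; ties do not set
  bits), mirror-padded borders, codes 0–255.
- **Quantization.**  32 equal-width bins over the in-mask range, per VOI.
  Texture matrices use the 13 unique offsets at Chebyshev distance 1;
  co-occurrences are pooled over offsets, symmetrized, normalized.
  Grey-level and run/zone/dependence indices are 1-based in weighted sums;
  GLDM dependence size is (dependent-neighbour count + 1).
- **First-order.**  Percentiles use linear interpolation; kurtosis is
  excess kurtosis; entropy/uniformity use a 32-bin histogram (base-2).
- **Degenerate VOIs** (empty region, < 2 voxels, or constant transformed
  intensity) impute 0 for every formula with a logged warning, keeping
  tables rectangular.  Undefined ratios in texture formulas (e.g.
  correlation of a constant region) impute 0.

## The selector

Stage 1 trains `n_fits = 50` L1-penalized logistic models
(scikit-learn liblinear, C = 1 — the library default penalty strength —
with a pinned per-fit RNG since liblinear permutes coordinates internally)
on stratified random 80% subject subsets, standardizing each subsample.
Every nonzero-coefficient feature enters the bag with multiplicity (a flag
switches to presence counting).  Stage 2 counts component names over the
bag and keeps the top (3, 3, 4, 8) per category, ties broken by registry
order; categories with fewer nonzero names keep all of them (logged).
Stage 3 materializes all features whose components are each selected, and
fits a standardized PCA (default 15 components, clamped to
min(n_train − 1, p) with a warning) on the training rows.

Standardize-then-PCA is the default because radiomic features span orders
of magnitude across transforms and formulas; center-only PCA would be
dominated by the largest-scale features.

The leakage contract — no stage reads held-out rows — is asserted directly:
randomizing all test-row values changes nothing in the `SelectorResult`.

## Benchmark protocol

`run_cv` draws a fresh stratified k-fold partition per trial; within each
fold the named selector, the PCA embedding and the classifier are all fit
on training rows only and the held-out fold is scored by ROC AUC (trapezoid
rule; equal to the Mann–Whitney U statistic over n₁n₂, verified against
pair counting).  The default protocol is 100 trials × 10-fold; the test
suites and the acceptance script use 10–20 repetitions of 5-fold, which
keeps every check inside a few minutes on one CPU at the reduced registry.
All cells of a comparison grid consume byte-identical partitions, so
selector/model differences are paired.  Both spread conventions are
reported: sd of per-trial means (the conventional ± number) and sd over all
fold scores.

Baselines are forced to 288 features: LASSO top-|coefficient| (plain top-k
ranking, which pads with next-largest magnitudes when fewer than k are
nonzero), RFE dropping 10% of remaining features per step (a tractability
choice at these dimensions), and variance thresholding; plus all-features
with and without the 15-dim PCA.  The six model families (L1 logistic,
linear SVM, MLP, XGBoost, random forest, ridge logistic) run at library
defaults — deliberately untuned, since hyperparameter search inside a
46-subject CV would itself overfit.

## Synthetic generators

**Planted tables** emulate the statistical structure the selector assumes:
46 subjects (25 vs 21), the reduced 4×5×6×12 registry (1,440 features;
counts (3, 3, 4, 8) still materialize 288), and two component-consistent
signal blocks — FLAIR and T1ce blocks over {t2_abnormality, tumor_core} ×
{log_1mm, haar_lll} × four formulas, 32 signal features in all.  Signal
features get a ±δ/2 class mean shift (default δ = 1 sd) and share a
per-block latent factor (pairwise ρ = 0.3); every column is then multiplied
by a log-normal scale (σ = 1) so that raw variance reflects scale rather
than class signal, as it does in real feature tables.  The block width is a
modelling statement, not a convenience: at n = 46 and p = 1,440 a single
δ = 1 feature is statistically indistinguishable from the extreme order
statistics of the noise columns, so any recoverable signal must be spread
over structurally aligned features — precisely the regime the method is
designed for.  The truth record (signal keys, planted component names) ships
with every table.

**Phantoms** are four-sequence volumes with nested ellipsoidal compartments
(necrotic core 0.40, enhancing rim 0.55, non-enhancing shell 0.68 of the
halo semi-axes; defaults 64³ grid, 22/18/15 mm halo, 32³ with ~11/9/8 mm in
the test suite).  Sequence intensities are plateau values per compartment
(enhancing bright and necrosis dark on T1ce; halo bright on FLAIR/T2), the
halo edge is a sigmoid in normalized ellipsoid radius whose physical width
is the *only* systematic class difference — 0.5 mm (sharp) vs 3 mm
(diffuse/infiltrative) — plus per-subject geometry jitter (±10% semi-axes,
±2 mm centre) and Gaussian noise (sd 0.02 of the intensity range).  The
emitted BraTS-style mask round-trips through the Otsu remap exactly on
noise-free phantoms because label 1 contains the dark core and the brighter
non-enhancing shell.

What the generators do **not** emulate: scanner/site effects, bias fields,
registration error, anatomical variability, partial-volume mixtures, or
realistic texture inside compartments.  Passing tests therefore demonstrate
the pipeline's statistical and algorithmic correctness under its own
assumptions — not clinical performance.

## Known limitations

- The exact membership of the 19-transform and 93-formula registries beyond
  the named members is a reconstruction; all counts and the selection
  machinery are independent of the particular membership.
- The necrosis/non-enhancing split assumes T1ce bimodality within BraTS
  label 1.
- Feature extraction is single-threaded NumPy; a 35,340-feature extraction
  takes a few seconds per subject at 32³ and scales roughly with voxel
  count.
- The benchmark reports no significance tests between cells (out of scope);
  the paired-partition design makes sign comparisons meaningful but
  multiple-comparison control is the caller's responsibility.
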
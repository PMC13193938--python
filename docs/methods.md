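# Methods

`habitatpipe` implements a habitat + peritumoral CT-radiomics analysis for
predicting early treatment response (objective response rate, ORR, under
mRECIST) and progression-free survival (PFS) in liver tumors, exercised
end to end on synthetic cohorts so that every stage is verifiable without
patient data. This note records the models, the synthetic study conditions,
the numerical conventions, and the design choices that were genuinely open.

## Problem and pipeline

Each patient contributes a portal-venous-phase CT volume (HU), a tumor mask
and a liver mask on an isotropic 1 mm grid, a clinical covariate table
(AFP, performance status, Child-Pugh, ...), a binary ORR label and a
censored PFS time. The pipeline:

1. **Preprocess** — resample to 1×1×1 mm (trilinear for intensities,
   nearest-neighbour for masks) and window to the liver window
   (level 45 HU, width 200 HU → [−55, 145] HU mapped to [0, 1]).
2. **Peritumoral shells** — rings at Euclidean distance (0, 3] and (0, 9] mm
   from the tumor margin, clipped to liver, minus an optional vessel
   exclusion mask, always disjoint from the tumor. Distance comes from the
   exact Euclidean distance transform with physical spacing, not iterated
   morphological dilation, because a metric definition is reproducible
   across implementations.
3. **Habitats** — tile each tumor with non-overlapping 3×3×3 blocks; every
   block whose center voxel is tumor yields a 19-dimensional local feature
   vector (first-order statistics of the 27-voxel neighbourhood: mean,
   median, min, max, range, variance, SD, skewness, kurtosis, energy, RMS,
   16-bin histogram entropy and uniformity on the windowed [0, 1] range,
   mean absolute deviation, 10th/90th percentiles, IQR, coefficient of
   variation, mean gradient magnitude). Blocks pooled over the *training*
   cohort are z-scored and clustered with K-means (k-means++, 10 restarts,
   tolerance 1e-4); the cluster count K maximizes the Calinski–Harabasz
   index over k = 2..10. Habitat indices are renumbered by ascending
   centroid mean intensity so `h1..hK` are comparable across patients.
   Pooled (not per-patient) fitting is required for habitat-indexed feature
   names to mean the same thing in every patient; a per-patient mode is not
   provided because nothing downstream could consume it coherently.
   The pooled block matrix is sorted lexicographically before fitting so
   patient order cannot influence the seeded initialization.
4. **Radiomics** — for each ROI (whole tumor, each habitat, each shell):
   14 shape descriptors plus 93 intensity/texture features — first-order
   (18), GLCM (24), GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5) — on the
   original image and, in the full configuration, on 8 one-level stationary
   Coiflet-1 wavelet sub-bands (LLL..HHH) and a sign-preserving logarithm
   transform: 14 + 93×10 = 944 features per ROI. Exact numerical parity
   with any other radiomics toolbox is not claimed; the catalogue covers the
   same feature classes and filter families and each matrix is tested
   against brute-force enumeration.
5. **Selection** (per region, training cohort only) — univariate filter
   (Shapiro–Wilk routes each feature to Welch t or Mann–Whitney U; keep
   p < 0.05, no multiplicity correction) → Pearson prune (|r| > 0.9, drop
   the larger-p member, visited in descending |r|) → greedy recursive
   elimination (repeatedly remove the feature with the highest mean |r| to
   the rest until that maximum falls below 0.75 or ≤ 20 remain) → mRMR
   (FCQ variant, top 15) → L1-penalized logistic regression with a
   100-point λ grid spanning four decades below λ_max and stratified
   10-fold CV.
6. **Models** — per region, four candidates (Random Forest, XGBoost, MLP,
   Extra Trees) tuned by stratified 5-fold grid search on AUC with SMOTE
   applied inside training folds only, refit on the SMOTE-augmented full
   training cohort; the internal-validation AUC picks the winner (ties:
   accuracy, then a fixed algorithm order). A clinical logistic model is
   built by univariable → multivariable screening at α = 0.05. The
   combined model is a logistic stacker over the best intratumoral-family
   model, the best peritumoral model and the clinical model.
7. **Evaluation** — AUC with DeLong variance and Wald 95% CI, paired DeLong
   tests, confusion metrics at the training-cohort Youden threshold
   (frozen for validation/test), continuous NRI and IDI, calibration curves
   with logistic recalibration slope, decision-curve net benefit, exact
   Shapley attributions, and Kaplan–Meier / log-rank PFS stratification at
   the combined model's training Youden cutoff.

The modeled positive class is **non-response (ORR−)** throughout, so a high
predicted probability means high risk of not responding; AUC is symmetric
to this choice, and the survival stratification labels patients above the
cutoff "high risk".

## Synthetic study conditions

The generator (`habitatpipe.synthetic`) emulates the data structure the
analysis assumes; its defaults are the study conditions used by the tests.

* **Anatomy.** A liver ellipsoid filling the grid (background
  Normal(100, 15) HU, inside the liver window), surrounding soft tissue at
  30 ± 12 HU, and a hypodense ellipsoidal tumor with per-axis radius drawn
  from 8–12 mm on a 48³ mm grid (tests use 40³/32³ grids where stated).
* **Habitats.** The tumor is partitioned into 3 concentric equal-volume
  subpopulations (configurable to sectoral wedges and to custom radial
  cuts) with mean HU (30, 65, 100) — core → periphery — within-class SD
  10 HU, and Gaussian-random-field texture with correlation lengths
  (5, 3, 1.5) mm: a homogeneous hypodense core grading into a fine-textured
  periphery that matches liver attenuation. Means 3.5 within-class SDs
  apart make the voxel intensity histogram multimodal. Clinical tumors
  often show strongly unequal subregion volumes; equal volumes are used
  here so every habitat ROI clears the texture-feature voxel floor at
  desk-scale tumor sizes.
* **Partial volume.** The piecewise mean map is blurred with a 1 mm
  Gaussian and region noise fields are cross-faded with the blurred
  indicators, emulating CT partial-volume softening. Without this, razor
  boundaries spawn a large "heterogeneous block" population whose variance
  and gradient features dominate the pooled K-means and absorb one cluster.
* **Response model.** Latent standard-normal scores z_rim and z_h2 modulate
  the rim noise amplitude (15·exp(0.3 z_rim) HU within the 3 mm rim) and
  the habitat-2 mean (+6 z_h2 HU). AFP is log-normal (median 200 ng/mL,
  log-SD 1.2). ORR is Bernoulli with
  logit p = b0 − 0.8·z(log AFP) + 1.5·z_rim + 1.0·z_h2, with b0 calibrated
  by root-finding so the realized prevalence matches the target 0.52 (the
  pooled two-center response rate scale). `rim_effect_size` etc. are
  log-odds coefficients; 0 disables an effect, and the realized
  standardized mean difference in rim texture between classes is a
  monotone function of the coefficient (≈ 0.6× at the defaults).
* **Survival.** PFS is exponential with responder median 11 months and the
  non-responder hazard multiplied by 2 (medians ≈ 11 vs 5.5 months,
  matching the order of the low-/high-risk medians the method is meant to
  separate). Censoring is independent: with probability 0.25 a patient is
  administratively censored uniformly before their event time.
* **Cohorts.** Center 1 (143 patients) splits 7:3 into training (100) and
  internal validation (43), stratified by ORR; center 2 (70) is external.

**What the generator does not emulate:** real organ anatomy, multiphase
acquisition, scanner/protocol batch effects (no harmonization step is
included, deliberately), segmentation error, correlated clinical
covariates, or non-exponential hazards. Passing tests therefore demonstrate
that the pipeline recovers structure it is pointed at under controlled
conditions — not clinical performance.

## Numerical conventions

* Windowing maps [−55, 145] HU linearly to [0, 1]; applying the window
  twice (with re-expressed bounds) is the identity.
* Gray-level discretization: fixed bin width 0.025 on the windowed scale
  (≈ 5 HU) for original and logarithm images, ROI-min anchored; wavelet
  sub-bands (whose range is not anchored) use a fixed 40-bin count over the
  ROI range. Gray-level counts are capped at 128 with a fixed-count
  fallback for pathological ranges.
* Texture matrices use distance 1 and the 13 unique 3-D directions; GLCM
  and GLRLM are averaged over directions; GLSZM zones use 26-connectivity;
  GLDM uses dependence α = 0 over the 26-neighbourhood.
* Shape: surface area and mesh volume come from marching cubes on a
  0.8 mm Gaussian anti-aliased copy of the mask, which suppresses the
  staircase bias of meshing a binary grid (sphere-surface error ~±2%,
  mesh volume within 5% down to r = 5 mm); voxel-count quantities, axis
  lengths (4√λ of the coordinate covariance), extent and maximum 3-D
  diameter (convex-hull vertices) use the raw mask.
* z-scoring uses population SD (ddof 0); zero-variance training columns
  are dropped from all cohorts and logged.
* K-means ties in habitat assignment go to the lowest habitat index;
  Youden ties go to the lower threshold; CH ties go to the smaller k.
* Youden thresholding predicts positive at score ≥ threshold; thresholds
  are midpoints of consecutive observed scores.
* DeLong: structural components with midranks (tie-corrected); identical
  score vectors short-circuit to z = 0, p = 1.
* Median survival: first observed time with S(t) ≤ 0.5 (NaN if never).
* Exact Shapley values enumerate all 2^M coalitions with
  background-marginal expectations (refused for M > 15); local accuracy
  holds to 1e-6.
* Degenerate inputs: ROIs under 27 voxels yield NaN sentinels (the
  pipeline imputes them with training-cohort means and counts them in the
  manifest, keeping cohort sizes fixed); zero-denominator confusion ratios
  return NaN sentinels; constant features take the Mann–Whitney path and
  are never selected.

## Design choices made where the design was open

* **λ rule.** The LASSO stage defaults to the 1-SE rule. With the plain
  CV-deviance minimizer, the planted-support simulation (3 informative /
  12 noise, n = 100) recovers all informative features but admits ~5 false
  positives on average; the 1-SE rule recovers 2.95/3 with ~1.2 false
  positives. `rule="min"` remains available.
* **Greedy recursive elimination.** The redundancy-reduction greedy is
  specified only loosely in the field; the canonical mean-absolute-
  correlation eliminator with a 0.75 stop and a 20-feature floor is used,
  with deterministic tie-breaks (univariate p, then name).
* **Stacker inputs.** The combined model is trained on out-of-fold
  training probabilities of its base models (cross-fitted), not
  resubstitution probabilities, so the stacker cannot learn base-model
  overfit. A small ridge (C = 1e3) keeps coefficients of non-informative
  base inputs identifiable at ~0.
* **Block-level habitat recovery.** On realistic partial-volume cohorts
  the adjusted Rand index between planted and recovered block labels is
  intrinsically capped (~0.3–0.5): tumor-surface and inter-habitat
  boundary blocks have genuinely ambiguous ground truth at 3³ resolution,
  and even an intensity-only oracle clustering tops out near 0.64. Full
  label recovery (ARI ≈ 1, asserted ≥ 0.8) is therefore tested on
  block-aligned phantoms with no straddling blocks, while cohort-level
  tests assert the selected K and partial alignment. The cluster-count
  recovery itself is robust: the CH scan selects k = 3 in 20/20 seeds
  under the default conditions.
* **Confusion-metric thresholds** are the training-cohort Youden cutoff
  per model, frozen for validation and test cohorts.
* **NRI** is the continuous (category-free) variant, as no clinical risk
  categories are defined.
* **Fisher routing** applies to 2×2 tables with any expected cell below 5;
  larger sparse tables stay on chi-square (flagged in the output), since no
  exact R×C test is available in the stack.

## Problem sizes

Test and acceptance runs use desk-scale conditions chosen once: 48³ mm
volumes with 8–12 mm tumor radii for the 143 + 70-patient end-to-end run
(completes in ~1.5 min on one CPU with the original-image feature
configuration; the full 944-feature catalogue is exercised on single
volumes), 40-patient cohorts over 20 seeds for cluster-count recovery, and
1000–2000-replicate nulls for type-I-error checks. The end-to-end
bit-reproducibility of the manifest is asserted on a reduced cohort
(20 + 8) through the identical code path.
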
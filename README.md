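# habitatpipe

Habitat and peritumoral CT-radiomics pipeline for predicting early treatment
response and progression-free survival in liver tumors.

Whole-tumor radiomics treats a heterogeneous tumor as one ROI. This package
implements the alternative: partition each tumor into *habitats* — subregions
of voxels with similar local imaging phenotype — and model response from
habitat-wise and peritumoral features alongside clinical covariates. It is
aimed at imaging-biomarker researchers who want every stage of such an
analysis (simulation, preprocessing, clustering, feature extraction,
selection, modeling, evaluation, survival) as tested, reusable code. Because
patient images from such studies are typically not shareable, the package
ships a synthetic-cohort generator that plants the statistical structure the
analysis assumes, so the entire pipeline is verifiable offline.

## Method

For each patient with CT volume $I$ (portal-venous, resampled to 1 mm³,
windowed to $[\mathrm{WL}{-}\mathrm{WW}/2,\ \mathrm{WL}{+}\mathrm{WW}/2] =
[-55, 145]$ HU with WL = 45, WW = 200) and tumor mask $T$:

* **Habitats.** Non-overlapping $3^3$ blocks with center voxel in $T$ yield
  19-dimensional local feature vectors (neighbourhood statistics including
  histogram entropy and energy). Blocks pooled over the training cohort are
  z-scored and clustered by K-means; the cluster count maximizes the
  Calinski–Harabasz index
  $\mathrm{CH}(k) = \frac{B/(k-1)}{W/(N-k)}$ over $k = 2..10$, where $B$ and
  $W$ are between- and within-cluster dispersions.
* **Peritumoral shells.** Rings at Euclidean distance $(0, 3]$ and
  $(0, 9]$ mm from the tumor margin, clipped to liver and disjoint from $T$.
* **Radiomics.** Per ROI (tumor, each habitat $h_k$, each shell): 14 shape +
  93 first-order/GLCM/GLRLM/GLSZM/GLDM/NGTDM features on the original image
  and optionally on 8 stationary Coiflet-1 wavelet sub-bands and a logarithm
  transform (944 features per ROI in full configuration).
* **Signature.** Per region, a five-stage training-cohort cascade:
  univariate test ($p<0.05$) → Pearson prune ($|r|>0.9$) → greedy
  redundancy elimination → mRMR (top 15) → LASSO-logistic with 10-fold CV;
  the nonzero-coefficient features and weights form the radiomics signature.
* **Models.** Per region: Random Forest, XGBoost, MLP and Extra Trees, tuned
  by stratified 5-fold grid search with SMOTE inside folds; the
  internal-validation AUC picks the winner. A combined model stacks the best
  intratumoral-family, best peritumoral and clinical (logistic) predictions.
* **Evaluation.** AUC with DeLong 95% CI and paired DeLong tests, NRI/IDI,
  calibration, decision curves, exact Shapley attributions; Kaplan–Meier /
  log-rank PFS stratification at the training-cohort Youden cutoff.

The modeled positive class is non-response (ORR−). See `docs/methods.md`
for conventions, synthetic study conditions and design rationale.

## Worked example

```bash
python analysis/01_simulate_cohort.py   # two-center synthetic cohort
python analysis/02_habitat_clustering.py
python analysis/03_run_pipeline.py      # full pipeline, ~2 min on one CPU
python analysis/04_evaluate_and_survival.py
```

`01` prints the cohort it simulated — e.g.

```
simulated 213 patients (143 + 70)
overall ORR 55.4% (118/213)
baseline variables differing between response groups (p<0.05): ['AFP']
```

meaning 143 center-1 patients (split 100 training / 43 internal validation)
plus 70 external patients, with AFP the only clinical covariate carrying a
planted response effect. `02` scans the cluster count:

```
Calinski-Harabasz scan over k=2..10: optimal k = 3
```

recovering the three planted tumor subpopulations. `03` runs the pipeline
end to end and reports, per model and cohort, discrimination such as

```
habitat    train=0.982  internal=0.816  external=0.751
combined   train=0.980  internal=0.909  external=0.848
```

i.e. the stacked combined model (habitat + peritumoral + clinical here)
leads on internal validation and stays within sampling error of the best
base model externally. `04` re-evaluates from
the written artifacts and stratifies survival at the training Youden cutoff
(0.530):

```
train     median PFS high-risk 4.3 vs low-risk 17.0 months (log-rank p=0.0000)
internal  median PFS high-risk 8.0 vs low-risk 12.0 months (log-rank p=0.0195)
```

High predicted non-response risk translates into significantly shorter
progression-free survival, which is the clinical point of the score. Tables
(AUC with CIs, DeLong/NRI/IDI comparisons, calibration bins, decision
curves, KM medians) are written under `results/`.

A CLI wraps the common entry points:

```bash
habitatpipe simulate --n 20 --seed 0 --out cohort/
habitatpipe shell --tumor t.nii.gz --liver l.nii.gz --mm 3 --out ring3.nii.gz
habitatpipe run-all --seed 1 --out run/
```

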
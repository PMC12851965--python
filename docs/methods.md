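# Methods

`gisthabitat` implements a subregional ("habitat") CT radiomics pipeline for
two-class prediction of the mitotic index (≤5 vs >5 per 50 HPF) in 2–5 cm
gastric GISTs, exercised end-to-end on a synthetic two-center phantom cohort.
This note documents the models, the tunable parameters and their defaults,
the numerical choices, and what the synthetic cohort does and does not show.

## Pipeline

For each case and CT phase (unenhanced, venous):

1. **Z-score normalization** over the whole volume, population SD
   (`preprocess.znormalize`). Constant volumes are an error.
2. **Resampling** to a 1 mm isotropic grid — cubic B-spline for the image,
   nearest-neighbour (re-binarized) for the mask, via SimpleITK
   (`preprocess.resample_isotropic`). Pairs already at 1 mm pass through
   unchanged.
3. **Unit rescaling** of within-ROI intensities to [0, 1]
   (`preprocess.rescale_unit`) — the clustering path only. ROI-only min/max
   is used because clustering operates on ROI voxels; feature extraction
   uses the z-scored (not unit-rescaled) image.
4. **Habitat clustering** (`habitat.cluster_subregions`): Lloyd's algorithm
   on scalar ROI intensities, initialized from the mean intensity of N
   equal-width bins over [0, 1] (bin b = [(b−1)/N, b/N), last bin closed;
   an empty bin falls back to its midpoint). No random restarts: the same
   input always gives the same partition. Convergence is zero assignment
   changes, capped at 300 iterations. Labels are renumbered density-
   descending: subregion 1 is the densest habitat, subregion N the least
   dense. The cluster count is selected by the downstream mean 5-fold CV
   AUC over candidates {3, 4, 5} (`habitat.select_cluster_count`), ties to
   the smallest N; a candidate whose subregions support feature extraction
   in fewer than 70% of cases fails and is excluded from the selection —
   on 2–5 cm lesions this is the usual fate of N > 3.
5. **Feature extraction** (`features.FeatureExtractor`): 1,045 named
   features per lesion per phase per region —
   original image: 18 first-order + 14 shape + 68 texture
   (GLCM 24, GLDM 14, GLRLM 16, GLSZM 14) = 100;
   8 stationary-wavelet sub-bands (coif1) × 86 (first-order + texture);
   2 Laplacian-of-Gaussian scales (σ = 1, 2 mm) × 86; and an LBP-3D code
   map × 85. Shape features come only from the original image. On the LBP
   code map TotalEnergy is omitted: at 1 mm isotropic spacing it duplicates
   Energy exactly, and dropping it keeps the bank at its documented size.
   Texture families use a fixed 32-bin equal-width discretization within
   the region (the images are z-scored, so HU-based bin widths would be
   meaningless). Directional families (GLCM, GLRLM) average feature values
   over the 13 unique 3-D directions; GLSZM uses 26-connected zones; GLDM
   uses 26-neighbour dependence counts with α = 0. Regions under 27 voxels
   yield a missing-feature record (texture matrices are ill-defined on tiny
   regions); affected cases are excluded from that region's model and
   logged.
6. **Feature screening**: (a) stability — features are re-extracted on
   masks perturbed by seeded one-voxel morphological patches
   (`features.jitter_mask`), emulating a second reader's outlines, and kept
   when the two-way random-effects absolute-agreement single-measure ICC,
   ICC(2,1), is strictly greater than 0.75; (b) redundancy — while any pair
   of retained features has |Spearman ρ| > 0.9, the member of the worst
   pair with the larger mean absolute correlation to the retained set is
   removed (ties to the lexicographically later name), making the output
   deterministic and order-free.
7. **Recursive Feature Addition** (`rfa_select.rfa`): greedy forward
   selection maximizing mean stratified 5-fold CV AUC of logistic
   regression, accepting a candidate only if it improves the incumbent by
   more than 0.001; stops on tolerance failure, decline, or exhaustion.
   Folds are fixed once per call (paired candidate comparisons); candidates
   are scanned in sorted-name order so results do not depend on column
   order. Oversampling of the minority class (with replacement, to 1:1)
   and feature standardization happen inside each training fold only.
8. **Models and evaluation** (`model_eval`, `experiment`): eight radiomics
   models (2 phases × {subregion 1–3, whole tumor}) plus a clinical model
   (sex, age, BMI, CEA, AFP, CA19-9, CA125, location one-hot, size), all
   logistic regression (effectively unpenalized: C = 10⁶, lbfgs, ≤1,000
   iterations, standardized features) on the oversampled center-1 cohort.
   The decision threshold is Youden's J on the training ROC and is carried
   unchanged to the other splits. "Validation" is the pooled out-of-fold
   prediction set of the seeded 5-fold CV on center 1 (no separate internal
   hold-out — the only leak-free reading of a CV-based internal
   validation); "test" is center 2. AUC is the rank statistic; its 95% CI
   is a stratified bootstrap percentile interval (2,000 replicates by
   default, seeded). Reports enforce SEN ≡ TPR and FPR ≡ 1 − SPE. Decision
   curves use NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) with treat-all/none
   references. Feature attributions are the exact Shapley values of a
   linear model under a feature-independence baseline:
   φ_ij = w_j (z_ij − mean(z_j)) on the logit scale, which satisfies
   additivity to machine precision.

## The synthetic cohort

No patient imaging is distributed, so every stage is exercised on a
generated two-center cohort (`synthetic_cohort`): 239 center-1 cases
(195 low / 44 high mitotic) and 129 center-2 cases (108/21), tumors 2–5 cm.
Clinical covariates are drawn from class/center-conditional marginals
(normal for continuous variables, categorical frequencies for sex and
location) with plausibility clipping; no between-covariate correlation is
modeled because only marginals are specified.

Each phantom is a rotated superellipsoid (exponent ~U(1.9, 2.3)) with
three nested, geometrically similar intensity components: a dense outer
shell (mean 1.10 abstract units), an intermediate shell (0.65), and a
hypodense core (0.45), all with SD 0.18 and draws clipped at ±2.5 SD.
The outer and intermediate shells share the non-core volume equally, so a
core-free tumor has a symmetric intensity mixture — which makes the
within-mask skewness magnitude grow monotonically with `core_fraction`.
Smoothing (σ = 0.5 voxel) uses normalized convolution separately inside
and outside the mask so boundary voxels are not dragged toward the dark
background; independent voxel noise (SD 0.12) is added afterwards. The
venous phase shares the geometry, adds a +0.9 enhancement inside the
tumor, pulls 55% of the core's deviation toward the intermediate shell
(enhancement masks intratumoral heterogeneity), and adds a smooth
perfusion field plus 15% more noise.

Planted class effects (sampled per case, clipped):

| latent parameter | low class | high class | interpretation |
|---|---|---|---|
| `core_fraction` | N(0.18, 0.05) | N(0.25, 0.06) | necrotic-core volume share |
| `flatness_target` | N(0.76, 0.09) | N(0.60, 0.10) | least/largest axis ratio |
| `skewness_target` | N(0.0, 0.15) | N(−2.0, 0.20) | within-core intensity asymmetry |

plus per-case component-mean offsets N(0, [0.025, 0.025, 0.03]) as
biological nuisance. The design was chosen so that the information
channels mirror the study structure: the whole-tumor model sees flatness
and core mass cleanly, but its histogram-level skewness channel is diluted
by the mixture variance and the mean-offset nuisance (both
location-sensitive), whereas subregion 3 — the hypodense habitat —
measures the core's skewness directly (skewness is location- and
scale-invariant). Both classes have a genuine core, so subregion 3 is a
clean core detector in every case. Consequence, verified by the test
suite: on unenhanced phantoms the subregion-3 model's external-test AUC
meets or exceeds the whole-tumor model's, and a skewness-family feature
ranks in the subregion-3 model's SHAP top 3, across seeded replicates. A
clairvoyant logistic model on the true (core_fraction, flatness) pairs
achieves external AUC ≈ 0.93 (Monte-Carlo design value), an upper
reference for image-based models.

What the phantoms do **not** emulate: organ background and neighbouring
structures, scanner- or protocol-specific noise and artifacts, DICOM
geometry, partial-volume effects at real slice thicknesses, reader
variability beyond the synthetic mask jitter, and any claim that the
planted effect sizes match patient biology. Passing tests therefore show
that the pipeline recovers structure it is designed to recover under
controlled conditions — not that the patient-data AUCs are reproduced.

## Numerical choices and degenerate inputs

- Population (not sample) SD in z-normalization; the difference is
  negligible at volume scale.
- K-means: an empty cluster keeps its previous centroid during iteration;
  clusters still empty at convergence are flagged and that subregion's
  features recorded missing.
- Half-open bin convention [(b−1)/N, b/N), last bin closed at 1, fixed for
  determinism.
- Kurtosis is non-excess (normal ≈ 3); skewness/kurtosis use population
  moments.
- ICC is undefined for zero-variance features → dropped with a warning;
  Spearman ρ undefined for constant features → dropped first with a
  warning.
- Fisher's exact test for r×c tables is a seeded Monte-Carlo
  Freeman-Halton permutation (scipy provides only 2×2); chi-square is the
  uncorrected Pearson statistic, matching the textbook Σ(O−E)²/E.
- Percent cells round half-up (decimal arithmetic) to match printed
  two-decimal tables.
- Written `.nii.gz` files fix the gzip mtime to 0 so identical seeds give
  identical checksums.

## Problem sizes used by the test suite and acceptance script

Cohort-scale checks run the reduced feature bank (first-order + shape,
no filtered images) on default 368-case cohorts; the full 1,045-feature
bank is exercised on single lesions and small cohorts. The nine-model
experiment in the analysis scripts and acceptance script uses a 185-case
cohort (120 + 65) with 200–500 bootstrap replicates. These sizes are the
package's own choices for routine runs; all components accept the
full-scale settings.

## Known limitations

- Habitat clustering is scalar-intensity only (by design, matching the
  bin-based initialization); multi-feature voxel clustering is out of
  scope.
- The texture implementation follows the standard IBSI-style definitions
  but is not certified against the IBSI phantom set; the first-order
  family is cross-checked against an independent in-package oracle.
- The wavelet transform is a single-level stationary decomposition with
  `coif1`; other wavelets/levels are not exposed.
- The LBP-3D variant is a simple 26-neighbour comparison code, not the
  spherical-harmonic formulation.
- `select_cluster_count` evaluates candidates with the full
  selection+model pipeline and is therefore expensive at cohort scale.
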
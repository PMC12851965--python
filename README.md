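# gisthabitat

Subregional ("habitat") CT radiomics for preoperative prediction of the
mitotic index in 2–5 cm gastric gastrointestinal stromal tumors (GISTs).

Risk stratification of small gastric GISTs hinges on the mitotic index
(≤5 vs >5 per 50 high-power fields), normally known only after resection.
Whole-tumor radiomics summarizes a lesion with one feature vector and
ignores intratumoral heterogeneity; habitat radiomics instead partitions
each tumor into intensity subregions and models them separately. This
package implements that pipeline as a tested library plus analysis
scripts, and — because no patient imaging is distributed — exercises it
end-to-end on a synthetic two-center phantom cohort (239 + 129 cases,
class splits 195:44 and 108:21) with planted, recoverable class effects.

## Method

For each lesion and phase (unenhanced / venous), images are z-score
normalized, resampled to 1 mm³, and the ROI intensities rescaled to
[0, 1]. The ROI is partitioned by K-means on voxel intensity with a
deterministic initialization: the [0, 1] range is split into N equal-width
bins and each bin's mean intensity seeds a centroid, so the same input
always yields the same partition; labels are ordered by decreasing
centroid (subregion 1 = densest tissue, subregion 3 = hypodense core).
N = 3 is selected among {3, 4, 5} by downstream cross-validated AUC.

From every region (subregions 1–3 and the whole tumor), 1,045 IBSI-style
features are extracted: first-order (18), shape (14, original image only),
GLCM/GLDM/GLRLM/GLSZM textures (68), and first-order + texture on 8
wavelet sub-bands, 2 Laplacian-of-Gaussian scales and an LBP-3D code map.
Features unstable under mask perturbation (ICC(2,1) ≤ 0.75) and redundant
pairs (|Spearman ρ| > 0.9) are removed; Recursive Feature Addition then
greedily grows a feature set, accepting the candidate that raises the mean
stratified 5-fold CV AUC of a logistic-regression base classifier by more
than 0.001. Final models are logistic regressions on the oversampled
(1:1) center-1 cohort, thresholded by Youden's J, and evaluated on
training, pooled out-of-fold validation and the external center-2 test
split with AUC (bootstrap 95% CI), ACC/SEN/SPE/TPR/FPR, precision–recall
and decision-curve analysis; per-feature attributions use the exact
closed-form Shapley values of a linear model.

See `docs/methods.md` for the full model description, parameter defaults
and the phantom-cohort design.

## Worked example

```bash
python analysis/01_simulate_cohort.py   # generate the two-center cohort
python analysis/02_cluster_habitats.py  # habitat clustering on one lesion
python analysis/03_extract_features.py  # feature tables under results/
python analysis/04_select_and_model.py  # nine models + report bundle
python analysis/05_cohort_table.py      # cohort-characteristics table
```

`02_cluster_habitats.py` partitions a high-mitotic phantom (30% hypodense
core, within-core skewness −2.0) and prints:

```
 subregion  centroid  n_voxels  mean_intensity  truth_core_overlap
         1    0.7112      3351          0.7112              0.0000
         2    0.4846      3824          0.4846              0.1564
         3    0.2964      3889          0.2964              0.6876
```

— three density-ordered habitats; the least-dense habitat (subregion 3)
captures the planted necrotic core (69% of its voxels are truth-core).

`04_select_and_model.py` fits the eight radiomics models plus the clinical
model on a 185-case cohort (seed 1) and prints:

```
           model  train_AUC  validation_AUC  test_AUC
        clinical      0.788           0.561     0.702
 unenhanced_sub1      0.929           0.897     0.882
 unenhanced_sub2      0.926           0.910     0.847
 unenhanced_sub3      0.978           0.952     0.944
unenhanced_whole      0.917           0.891     0.891
     venous_sub1      0.905           0.874     0.788
     venous_sub2      0.878           0.852     0.768
     venous_sub3      0.600           0.574     0.591
    venous_whole      0.881           0.863     0.779
```

The qualitative structure the generator plants is recovered: on unenhanced
images the subregion-3 (hypodense-core) model outperforms the conventional
whole-tumor model, while in the venous phase contrast enhancement
homogenizes the core and the subregional advantage collapses. SHAP ranks a
skewness/shape signature at the top of the subregion-3 model, mirroring
the planted within-core asymmetry and flattened-geometry effects.

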
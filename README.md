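# segrobust

Interobserver and interdisciplinary segmentation-variability analysis for
CT radiomics.

When several experts contour the same tumor — particularly a low-contrast
one, such as pancreatic cancer on contrast-enhanced CT — their delineations
differ, and every radiomic feature computed downstream inherits that
uncertainty. Worse, the differences can be systematic between professional
disciplines (radiation oncologists tend to contour larger volumes and more
consistently than radiologists). `segrobust` is a reusable pipeline for
quantifying both effects: it builds a per-patient consensus volume, grades
each observer's agreement with it, extracts a fixed 1277-feature radiomic
panel per delineation, and scores every feature's robustness to the
observer variability — overall and per discipline. It is aimed at radiomics
researchers who need to know *which* features survive segmentation
uncertainty before using them in a model.

## The methods at its core

- **Consensus**: STAPLE — an EM algorithm over a latent true segmentation
  T with per-observer sensitivity p_j and specificity q_j; the consensus is
  the posterior foreground probability binarized at 0.5.
- **Agreement**: Dice similarity coefficient
  DSC = 2|A∩B| / (|A| + |B|), graded High (≥ 0.85), Medium (≥ 0.70),
  Low (≥ 0.5), Very Low (< 0.5); disciplines compared by a paired
  two-tailed t-test on per-patient discipline means.
- **Features**: 1277 features per (image, mask) pair — 143 from the
  original image (24 first order, 17 shape, 26 GLCM, 16 GLRLM, 22
  NGTDM/NGLDM, 16 GLSZM, 22 IVH) and 126 from each of 9 filtered images
  (Laplacian of Gaussian and 8 undecimated 3D wavelet subbands; shape is
  filter-invariant). Preprocessing: 5 mm isotropic windowed-sinc
  resampling, fixed bin width 25, texture matrices merged over the 13
  symmetric 3D directions at voxel offset 1. See
  `docs/feature_reference.md` for the frozen feature lists.
- **Robustness**: intraclass correlation for a two-way random-effects
  model with single measurements and absolute agreement,

      ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),

  computed from explicit ANOVA sums of squares; a feature is robust when
  ICC > 0.75. Discipline ICCs are compared per filter with a Wilcoxon
  signed-rank test, and within-class robustness *rankings* are compared
  between disciplines by rank-vs-rank least squares (slope, R²).

Because no multi-observer CT dataset ships with the package, a synthetic
cohort generator reproduces the study design: phantom tumors (smooth
random blobs, ~50 ± 15 cm³) in noisy low-contrast volumes, contoured by 6
simulated observers in 2 disciplines, where discipline B contours smaller
volumes (bias 0.66) with larger boundary noise than discipline A. Every
stage also runs on user-supplied NIfTI cohorts via a plain-text manifest.

## Worked example

```python
from segrobust import (CohortConfig, generate_cohort,
                       compare_disciplines_dsc, compare_volumes)
from segrobust.consensus import per_patient_agreement

cohort = generate_cohort(CohortConfig(master_seed=1))   # 21 patients, 6 observers
records, summary, consensus = per_patient_agreement(cohort)
print(records.head(6).to_string(index=False))

cmp = compare_disciplines_dsc(records)
print(f"mean DSC A = {cmp['mean_dsc_a']:.3f} +/- {cmp['sd_dsc_a']:.3f}")
print(f"mean DSC B = {cmp['mean_dsc_b']:.3f} +/- {cmp['sd_dsc_b']:.3f}")
print(f"paired t p-value = {cmp['p_value']:.2e}")
```

prints

```text
patient_id observer_id discipline  volume_cm3      dsc  grade
       P00          A1          A   53.530025 0.760470 Medium
       P00          A2          A   53.530025 0.841757 Medium
       P00          A3          A   53.530025 0.825116 Medium
       P00          B1          B   35.330250 0.641727    Low
       P00          B2          B   35.330250 0.651253    Low
       P00          B3          B   35.330250 0.678587    Low

mean DSC A = 0.830 +/- 0.021
mean DSC B = 0.685 +/- 0.023
paired t p-value = 1.17e-16
```

Each row is one observer's delineation of one patient: its volume, its
Dice overlap with the 6-observer STAPLE consensus, and the agreement
grade. The summary lines show the interdisciplinary effect this package
exists to measure — discipline A agrees with the consensus substantially
better than discipline B (0.830 vs 0.685), B contours smaller volumes
(here 34.1 vs 51.7 cm³ on average), and the paired test confirms the gap
is systematic across patients, not noise.

The feature-robustness half continues:

```python
from segrobust.pipeline import extract_cohort_features
from segrobust.robustness import feature_icc_table, robust_summary

feats = extract_cohort_features(cohort)          # 1277 features x 126 masks
groups = {p.observer_id: p.discipline for p in cohort.config.observers}
table, info = robust_summary(feature_icc_table(feats, groups))
print(info)
# {'n_robust_A': 355, 'n_robust_B': 182, ..., 'n_robust_A_and_B': 166}
```

i.e. 355 of 1277 features are robust (ICC > 0.75) to discipline-A
variability but only 182 to discipline-B variability, with 166 robust to
both — the discipline that contours less consistently leaves far fewer
usable features.

The same study runs from the shell:

```sh
segrobust run --seed 1 --out report/          # simulate -> consensus -> extract -> ICC
segrobust simulate --seed 1 --out cohort/     # or stage by stage via a manifest
segrobust consensus --manifest cohort/manifest.tsv --out consensus/
segrobust extract --manifest cohort/manifest.tsv --out features.tsv
segrobust robustness --features features.tsv --manifest cohort/manifest.tsv --out rob/
```

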
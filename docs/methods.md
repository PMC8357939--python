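# Methods

`segrobust` quantifies how interobserver and interdisciplinary tumor
delineation variability propagates into CT radiomic features. The pipeline
runs in four stages: (1) a cohort of images with one binary tumor mask per
observer, either simulated or user-supplied; (2) a per-patient consensus
segmentation (STAPLE) and Dice-based agreement grading; (3) a 1277-feature
radiomic panel per (patient, observer) mask; (4) per-feature ICC(2,1)
robustness, computed for all observers jointly and per discipline, with
discipline comparisons and rank-agreement regressions.

## Consensus segmentation (STAPLE)

Given J binary delineations of one patient, STAPLE treats the true
segmentation as a latent per-voxel indicator T_i and each observer j as a
Bernoulli channel with sensitivity p_j = P(D_ij = 1 | T_i = 1) and
specificity q_j = P(D_ij = 0 | T_i = 0). EM alternates a posterior
(E) step

    W_i = f · Π_j p_j^{D_ij} (1−p_j)^{1−D_ij} /
          [f · Π_j p_j^{D_ij}(1−p_j)^{1−D_ij} + (1−f) · Π_j q_j^{1−D_ij}(1−q_j)^{D_ij}]

with a (M) step re-estimating (p_j, q_j) from the posterior weights.

Numerical choices, all configurable:

- Initialization p_j = q_j = 0.99999; global scalar prior f = mean
  foreground fraction over the observers (standard practice; a spatially
  varying prior is deliberately not used).
- Convergence when max |Δp_j|, |Δq_j| < 1e-6, at most 100 iterations;
  p, q are clamped to [1e-8, 1 − 1e-8] to keep the E-step defined.
- Consensus = posterior ≥ 0.5 (ties to foreground).
- The EM sums run on the bounding box of the union of all masks plus a
  5-voxel margin. Voxels never marked by any observer cannot enter the
  consensus (their posterior is below the prior, which is below 0.5), and
  including arbitrarily much empty background only inflates the
  specificity estimates; the posterior for the all-background decision
  pattern is still reported on the full grid.
- Consensus and Dice run on the native (pre-resampling) grid, since
  contours are drawn on native images; resampling is purely a
  feature-extraction concern.

Dice agreement DSC = 2|A∩B|/(|A|+|B|) of each observer against the
consensus is graded High (≥ 0.85), Medium ([0.70, 0.85)), Low
([0.5, 0.7)), Very Low (< 0.5). DSC of two empty masks is defined as 1
(never reached in normal runs). Discipline DSCs and volumes are compared
with a paired two-tailed t-test on per-patient discipline means; if all
paired differences are identical the statistic degenerates (t = 0, p = 1
for zero difference; p = 0 otherwise), which is reported rather than NaN.

## Radiomic panel

Images are resampled to isotropic voxels (default 5 mm) with a separable
Lanczos-windowed sinc (radius 3 source voxels per axis, weights normalized
so constants are reproduced exactly); masks with linear interpolation of
the 0/1 field thresholded at 0.5, ties to foreground — this preserves
volume at coarse targets better than nearest neighbor. Ten filtered images
feed the panel: the original, a Laplacian of Gaussian (analytic kernel
sampled at voxel centers, σ = 5 mm by default — one voxel at target
spacing; LoG features are scale-sensitive, so this default is prominent
and configurable), and the 8 subbands of a single-level undecimated
separable 3D wavelet transform (Coiflet-1 by default; undecimated keeps
the grid geometry so the mask applies unchanged).

Gray levels use fixed bin width 25 anchored at the ROI minimum, applied
independently per filtered image (filtered responses are signed, so an
absolute anchor would be undefined). Texture matrices are merged over the
13 symmetric directions of the 26-neighborhood at voxel offset 1 (GLCM
symmetrized, GLRLM direction-merged); GLSZM zones and NGLDM dependencies
use 26-connectivity. The per-class feature lists (24 first order, 17
shape, 26 GLCM, 16 GLRLM, 5 + 17 NGTDM/NGLDM, 16 GLSZM, 22 IVH) are
frozen in `feature_reference.md`; totals are 143 for the original image,
126 per filtered image, 1277 overall.

Degenerate-ROI conventions are fixed per feature: entropy-like features
are 0 for a single gray level; variance-normalized features are 0 when the
variance vanishes; a single-voxel ROI yields the constant-ROI limits for
pair-based matrices (no pairs → the degenerate one-cell distribution)
rather than an error.

## Feature robustness: ICC(2,1)

Each feature yields a patients × observers rating matrix. The two-way
random-effects, single-measurement, absolute-agreement intraclass
correlation is

    ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

with mean squares computed from explicit sums of squares — not a generic
linear-model fit — so the estimator is transparent and testable against an
independent ANOVA decomposition (and cross-checked against `pingouin`'s
ICC(A,1) in the tests). Negative ICCs are reported as computed (clipping
would hide pathology) and are never robust; a vanishing denominator yields
a flagged NaN, excluded from paired tests and rankings and counted
non-robust. A feature is robust when ICC strictly exceeds 0.75 — the
strict inequality follows the definition adopted here, and the threshold
is configurable.

Per-filter discipline differences use the Wilcoxon signed-rank test on the
paired (ICC_A, ICC_B) values of each feature, dropping zero differences;
the exact null distribution is used for ≤ 25 untied differences, the
normal approximation otherwise. Rank agreement regresses, within each
feature class of the original image, discipline-B robustness ranks on
discipline-A ranks (average ranks for ties, ordinary least squares),
reporting slope and R².

## Synthetic cohort: what it emulates

The generator reproduces the *study design*, not anatomy: 21 patients,
tumor volumes ~N(50, 15²) cm³ (truncated at ±3 SD), 5 mm slices with
sub-mm (0.85 mm) in-plane spacing, low tumor contrast (30 intensity units
against noise of comparable scale), and 6 observers in 2 disciplines.

- **Tumor**: a star-convex blob with radius field
  R(θ, φ) = R₀·exp(0.10·g(θ, φ)), g a unit-variance Gaussian random field
  from orthonormal real spherical harmonics of degree 2–4; R₀ is set by
  continuum-volume quadrature so the realized volume matches the draw.
- **Image**: background level + contrast × indicator + noise, where the
  noise term combines white noise, smoothed texture and a mild gradient,
  all proportional to `image_noise_sd` — at zero noise the image is
  exactly two-valued, which the tests exploit.
- **Observer**: the truth surface is displaced by a smooth radial field
  (degrees 1–6, pointwise SD = `boundary_noise_sd` mm, ≈ 25° angular
  correlation — human contour errors are spatially correlated, and
  independent per-voxel label noise would make the consensus trivially
  accurate), then uniformly dilated/eroded to the configured volume bias.
  Implementation: threshold the (signed distance + noise) level set so
  that exactly round(bias × |truth|) voxels are selected. Smooth fields
  are realized on a fixed 64 × 128 (θ, φ) lookup grid (step ≈ 3°, far
  below the smallest angular wavelength of the degree ≤ 6 basis) and
  bilinearly interpolated at voxel directions.
- **Seeds**: every patient and observer derives its own
  `numpy.random.SeedSequence` from (master_seed, patient index, observer
  index), so cohorts are pure functions of the config and growing the
  cohort never reshuffles existing patients.

Default profiles — discipline A: volume bias 1.0, boundary noise 4.5 mm;
discipline B: bias 0.66, noise 5.5 mm — were chosen so the simulated
agreement levels land near those reported for radiation-oncology-like and
radiology-like observers (mean DSC ≈ 0.82 vs ≈ 0.69) while keeping B both
more conservative and noisier than A. This calibration provides realism
only; tests assert directions of effects, never these magnitudes.

What the generator does **not** model: anatomical context and organ
boundaries, partial-volume blur at the tumor edge, patient-to-patient
differences in contouring *difficulty* (so across-patient DSC spread is
narrower than in real data), intra-observer variability, and any
review/editing of outlier contours. Passing tests therefore demonstrate
that the pipeline recovers the statistical structure it is pointed at —
not that real interobserver data would show the same magnitudes.

## Problem sizes in tests and scripts

Unit tests run on reduced cohorts (≈ 12 cm³ tumors on 64×64×16 grids) for
speed; the acceptance checks of effect directions use the full default
design (21 patients, 128×128×24 native grids) over 20 master seeds, and
`scripts/acceptance.py` reports one full study plus direction-stability
over 10 seeds. These sizes are the package's chosen defaults for a
reproducible desk-scale study.

## Known limitations

- The STAPLE probability map is binarized for all downstream use;
  probabilistic weighting of features is out of scope.
- Only ICC(2,1) is implemented (the form appropriate for random raters and
  absolute agreement); other ICC variants and confidence intervals are not
  provided.
- Surface-distance agreement metrics (Hausdorff etc.) are not computed.
- Oblique NIfTI affines are rejected rather than resliced; reorient
  externally if needed.
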
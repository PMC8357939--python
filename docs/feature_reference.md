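# Feature reference

The panel computed by `segrobust.features.extract_panel` is frozen: with the
default configuration it contains exactly **1277** features — 143 from the
original image and 126 from each of the 9 filtered images (LoG and the 8
wavelet subbands; shape features are filter-invariant and counted once).

Feature ids are `"{filter}/{name}"` with filters
`original, log, LLL, HLL, LHL, HHL, LLH, HLH, LHH, HHH`.

All intensity statistics are computed on the in-mask voxels of the
(filtered) image after isotropic resampling (default 5 mm). Gray levels for
texture and histogram entropy use fixed-bin-width discretization (default
width 25) anchored at the ROI minimum:
`level(v) = floor((v − min_ROI) / width) + 1`.

## First order (24)

minimum, maximum, mean, range, variance, standard_deviation, skewness,
kurtosis (excess), median, percentile10, percentile25, percentile75,
percentile90, interquartile_range, mean_absolute_deviation,
robust_mean_absolute_deviation (values within [P10, P90]),
median_absolute_deviation (mean |x − median|), energy, total_energy
(energy × voxel volume), root_mean_square, coefficient_of_variation,
quartile_coefficient_of_dispersion, entropy (bits, discretized histogram),
uniformity.

Variance/moments are population moments (divide by N). Ratio features with
a vanishing denominator (constant ROI) are defined as 0.

## Shape (17) — original image only

volume, filled_volume (holes closed), surface_area,
surface_to_volume_ratio, sphericity, compactness1, compactness2,
spherical_disproportion, major_axis_length, minor_axis_length,
least_axis_length (4·√eigenvalue of the voxel-center covariance),
elongation, flatness, max_3d_diameter, max_2d_diameter_axial (xy),
max_2d_diameter_coronal (xz), max_2d_diameter_sagittal (yz).

Surface area uses the marching-cubes mesh by default; an exposed
voxel-face-counting definition is available via `surface="voxel"`.
Sphericity and the compactness family derive from the selected surface.

## GLCM (26) — prefix `glcm_`

Merged symmetric co-occurrence matrix over the 13 unique directions of the
26-neighborhood (voxel offset 1 by default): energy, joint_entropy,
joint_maximum, joint_average, joint_variance, contrast, dissimilarity,
inverse_difference, inverse_difference_norm, inverse_difference_moment,
inverse_difference_moment_norm, inverse_variance, sum_average,
sum_variance, sum_entropy, difference_average, difference_variance,
difference_entropy, autocorrelation, cluster_tendency, cluster_shade,
cluster_prominence, correlation, haralick_correlation,
first_info_correlation, second_info_correlation.

## GLRLM (16) — prefix `glrlm_`

Run-length matrix merged over the same 13 directions: short_run_emphasis,
long_run_emphasis, gray_level_nonuniformity, gray_level_nonuniformity_norm,
run_length_nonuniformity, run_length_nonuniformity_norm, run_percentage
(runs / (voxels × 13)), low_gray_level_emphasis, high_gray_level_emphasis,
short_run_low_gray_emphasis, short_run_high_gray_emphasis,
long_run_low_gray_emphasis, long_run_high_gray_emphasis,
gray_level_variance, run_length_variance, run_entropy.

## GLSZM (16) — prefix `glszm_`

Size-zone matrix with 26-connected zones: small_area_emphasis,
large_area_emphasis, gray_level_nonuniformity,
gray_level_nonuniformity_norm, zone_size_nonuniformity,
zone_size_nonuniformity_norm, zone_percentage, low_gray_level_emphasis,
high_gray_level_emphasis, small_area_low_gray_emphasis,
small_area_high_gray_emphasis, large_area_low_gray_emphasis,
large_area_high_gray_emphasis, gray_level_variance, zone_size_variance,
zone_entropy.

## NGTDM (5) + NGLDM (17) — prefixes `ngtdm_`, `ngldm_`

26-neighborhood, coarseness parameter α = 0.

NGTDM: coarseness (capped at 1e6 when the denominator vanishes), contrast,
busyness, complexity, strength. Voxels without any in-mask neighbor are
excluded.

NGLDM: low_dependence_emphasis, high_dependence_emphasis,
low_gray_count_emphasis, high_gray_count_emphasis,
low_dependence_low_gray_emphasis, low_dependence_high_gray_emphasis,
high_dependence_low_gray_emphasis, high_dependence_high_gray_emphasis,
gray_level_nonuniformity, gray_level_nonuniformity_norm,
dependence_count_nonuniformity, dependence_count_nonuniformity_norm,
dependence_count_percentage (fraction of voxels with a complete in-mask
26-neighborhood), gray_level_variance, dependence_count_variance,
dependence_count_entropy, dependence_count_energy. Dependence counts use
j = k + 1 in the emphasis formulas (k equal-level in-mask neighbors).

## IVH (22) — prefix `ivh_`

Computed on the raw (filtered) in-mask intensities:

- `vx10 … vx90` (9): volume fraction with intensity ≥ the relative
  intensity x% of the ROI range,
- `ix10 … ix90` (9): intensity (absolute units) at volume fraction x% —
  the minimum intensity of the hottest x% of the volume,
- `v10_minus_v90`, `i10_minus_i90`: range summaries,
- `auc`: area under the V(x) curve on a 1%-step grid,
- `v_abs_0`: volume fraction at or above absolute intensity 0.
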
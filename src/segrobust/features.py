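"""IBSI-style radiomic feature engine: a fixed 1277-feature panel.

The panel is computed per (image, mask) pair after isotropic resampling
(default 5 mm, windowed-sinc for the image, linear + 0.5 threshold for the
mask). Ten image filters are applied — the original image, a 3D Laplacian
of Gaussian, and the 8 subbands of a single-level undecimated separable 3D
wavelet transform (LLL ... HHH, low/high per axis in (x, y, z) order).

Per filtered image the engine computes, inside the (resampled) mask:

=================  =====  =========================================
class              count  notes
=================  =====  =========================================
first order          24   intensity statistics
shape                17   original image only (filter-invariant)
GLCM                 26   merged over 13 symmetric 3D directions
GLRLM                16   merged over 13 symmetric 3D directions
NGTDM + NGLDM      5+17   26-neighborhood
GLSZM                16   26-connected zones
IVH                  22   intensity-volume histogram
=================  =====  =========================================

giving 143 features for the original image and 126 per filtered image
(shape excluded), 1277 in total. Gray levels are discretized with a fixed
bin width (default 25 intensity units) anchored at the ROI minimum, which
keeps the rule well-defined for signed filter responses.

The exact per-class feature lists are frozen in ``docs/feature_reference.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .image_model import BinaryMask, ImageVolume, resample_isotropic

__all__ = [
    "ExtractionConfig",
    "QuantizedROI",
    "WAVELET_SUBBANDS",
    "DIRECTIONS_13",
    "log_filter",
    "wavelet_decompose",
    "discretize",
    "first_order_features",
    "shape_features",
    "texture_features",
    "ivh_features",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "ngtdm_table",
    "ngldm_matrix",
    "build_filter_bank",
    "extract_from_bank",
    "extract_panel",
    "PANEL_CLASS_COUNTS",
    "expected_panel_size",
]

WAVELET_SUBBANDS = ("LLL", "HLL", "LHL", "HHL", "LLH", "HLH", "LHH", "HHH")

DEFAULT_FILTERS = ("original", "log") + WAVELET_SUBBANDS

#: The 13 unique symmetric directions of the 26-neighborhood (the other 13
#: are their negatives and are folded in by symmetrization).
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

PANEL_CLASS_COUNTS = {
    "FirstOrder": 24,
    "Shape": 17,
    "GLCM": 26,
    "GLRLM": 16,
    "NGTDM_NGLDM": 22,
    "GLSZM": 16,
    "IVH": 22,
}


@dataclass(frozen=True)
class ExtractionConfig:
    """Preprocessing and discretization settings of the feature panel."""

    target_spacing: float = 5.0  # mm, isotropic
    bin_width: float = 25.0  # intensity units
    neighborhood_offset: int = 1  # voxels
    filters: tuple[str, ...] = DEFAULT_FILTERS
    log_sigma_mm: float = 5.0
    wavelet_family: str = "coif1"
    surface_method: str = "mesh"  # 'mesh' (marching cubes) or 'voxel' (face count)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.neighborhood_offset < 1:
            raise ValueError("neighborhood_offset must be >= 1")
        if len(set(self.filters)) != len(self.filters):
            raise ValueError("filter names must be unique")
        for f in self.filters:
            if f not in ("original", "log") + WAVELET_SUBBANDS:
                raise ValueError(f"unknown filter {f!r}")


def expected_panel_size(config: ExtractionConfig) -> int:
    per_filter = sum(PANEL_CLASS_COUNTS.values()) - PANEL_CLASS_COUNTS["Shape"]
    n = 0
    for f in config.filters:
        n += per_filter
        if f == "original":
            n += PANEL_CLASS_COUNTS["Shape"]
    return n


@dataclass
class QuantizedROI:
    """Discretized gray levels restricted to a mask.

    ``levels`` is an integer grid with 0 outside the ROI and consecutive
    levels 1..n_levels inside; level(v) = floor((v - min_ROI)/bin_width) + 1.
    """

    levels: np.ndarray
    n_levels: int
    bin_width: float
    roi_min: float

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def voxel_count(self) -> int:
        return int((self.levels > 0).sum())

    def level_values(self) -> np.ndarray:
        """In-mask levels as a flat array."""
        return self.levels[self.levels > 0]


# ---------------------------------------------------------------------------
# Image filters
# ---------------------------------------------------------------------------

def log_filter(vol: ImageVolume, sigma_mm: float) -> ImageVolume:
    """3D Laplacian-of-Gaussian response at physical scale ``sigma_mm``.

    Convolves with the analytic LoG kernel sampled at voxel centers
    (truncated at 4 sigma, scaled by the voxel volume to approximate the
    continuous convolution) with the residual DC removed, so constants map
    exactly to zero.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be > 0")
    spacing = np.array(vol.spacing)
    half = np.maximum(np.ceil(4.0 * sigma_mm / spacing).astype(int), 1)
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    r2 = x * x + y * y + z * z
    s2 = sigma_mm**2
    gauss = np.exp(-r2 / (2 * s2)) / ((2 * np.pi) ** 1.5 * sigma_mm**3)
    kernel = (r2 / s2 - 3.0) / s2 * gauss * np.prod(spacing)
    kernel -= kernel.mean()  # exact zero response to constants
    out = ndimage.convolve(vol.values, kernel, mode="nearest")
    return ImageVolume(out, vol.spacing, vol.origin)


def wavelet_decompose(vol: ImageVolume, family: str = "coif1") -> dict[str, ImageVolume]:
    """Single-level undecimated separable 3D wavelet transform.

    Returns the 8 subbands labeled LLL..HHH (low/high pass per axis in
    (x, y, z) order), each on the input grid. Axes with odd length are
    edge-padded to even length for the stationary transform and cropped
    back.
    """
    wav = pywt.Wavelet(family)
    data = np.asarray(vol.values, np.float64)
    if min(data.shape) < wav.dec_len:
        raise ValueError(
            f"volume shape {data.shape} smaller than the {family} filter "
            f"length {wav.dec_len}"
        )
    pad = [(0, n % 2) for n in data.shape]
    padded = np.pad(data, pad, mode="edge") if any(p[1] for p in pad) else data
    coeffs = pywt.swtn(padded, wav, level=1)[0]
    crop = tuple(slice(0, n) for n in data.shape)
    out = {}
    for key, arr in coeffs.items():
        label = "".join("L" if c == "a" else "H" for c in key)
        out[label] = ImageVolume(arr[crop], vol.spacing, vol.origin)
    return out


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(vol: ImageVolume, mask: BinaryMask, bin_width: float) -> QuantizedROI:
    """Fixed-bin-width discretization anchored at the ROI minimum."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    ind = mask.indicator
    if not ind.any():
        raise ValueError("cannot discretize an empty mask")
    vals = vol.values[ind]
    lo = float(vals.min())
    # the level grid is cropped to the ROI bounding box: every texture
    # definition only involves in-mask voxels and their neighbors
    idx = np.argwhere(ind)
    box = tuple(slice(a, b + 1) for a, b in zip(idx.min(axis=0), idx.max(axis=0)))
    sub = ind[box]
    levels = np.zeros(sub.shape, dtype=np.int32)
    levels[sub] = np.floor((vol.values[box][sub] - lo) / bin_width).astype(np.int32) + 1
    return QuantizedROI(levels, int(levels.max()), float(bin_width), lo)


# ---------------------------------------------------------------------------
# First-order features
# ---------------------------------------------------------------------------

def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def first_order_features(
    vol: ImageVolume, mask: BinaryMask, bin_width: float = 25.0
) -> dict[str, float]:
    """24 intensity statistics of the in-mask voxels.

    Entropy and uniformity are computed on the fixed-bin-width histogram;
    all other statistics use the raw intensities. Scale-free ratios
    (coefficient of variation, quartile dispersion, skewness, kurtosis)
    are defined as 0 when their denominator vanishes.
    """
    x = vol.values[mask.indicator].astype(np.float64)
    if x.size == 0:
        raise ValueError("empty mask")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = float(np.sqrt(var))
    p10, p25, p50, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))
    centered = x - mean
    skew = float((centered**3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float((centered**4).mean() / sd**4 - 3.0) if sd > 0 else 0.0
    robust = x[(x >= p10) & (x <= p90)]
    energy = float((x**2).sum())
    q = discretize(vol, mask, bin_width)
    hist = np.bincount(q.level_values())[1:].astype(np.float64)
    p = hist / hist.sum()
    return {
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "mean": mean,
        "range": float(x.max() - x.min()),
        "variance": var,
        "standard_deviation": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "median": p50,
        "percentile10": p10,
        "percentile25": p25,
        "percentile75": p75,
        "percentile90": p90,
        "interquartile_range": p75 - p25,
        "mean_absolute_deviation": float(np.abs(centered).mean()),
        "robust_mean_absolute_deviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "median_absolute_deviation": float(np.abs(x - p50).mean()),
        "energy": energy,
        "total_energy": energy * vol.voxel_volume_mm3,
        "root_mean_square": float(np.sqrt((x**2).mean())),
        "coefficient_of_variation": sd / mean if abs(mean) > 1e-12 else 0.0,
        "quartile_coefficient_of_dispersion": (
            (p75 - p25) / (p75 + p25) if abs(p75 + p25) > 1e-12 else 0.0
        ),
        "entropy": _entropy_bits(p),
        "uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# Shape features
# ---------------------------------------------------------------------------

def _voxel_face_area(ind: np.ndarray, spacing) -> float:
    """Surface area by counting exposed voxel faces."""
    sp = np.asarray(spacing, float)
    face = [sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]]
    padded = np.pad(ind, 1)
    total = 0.0
    for ax in range(3):
        diff = np.diff(padded.astype(np.int8), axis=ax)
        total += np.abs(diff).sum() * face[ax]
    return float(total)


def _mesh_area(ind: np.ndarray, spacing) -> float:
    """Surface area of the marching-cubes mesh at iso-level 0.5."""
    from skimage import measure

    padded = np.pad(ind.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return float(measure.mesh_surface_area(verts, faces))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 64:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) clouds: fall through
    return float(pdist(points).max())


def shape_features(mask: BinaryMask, surface: str = "mesh") -> dict[str, float]:
    """17 geometry descriptors of a binary mask.

    ``surface`` selects the surface-area definition: ``'mesh'`` (marching
    cubes, default) or ``'voxel'`` (exposed voxel-face counting). Axis
    lengths come from the principal components of the voxel centers
    (length = 4 sqrt(eigenvalue), the axis of the equivalent ellipsoid).
    """
    ind = mask.indicator
    if not ind.any():
        raise ValueError("empty mask")
    sp = np.asarray(mask.spacing, float)
    voxvol = float(np.prod(sp))
    n = int(ind.sum())
    volume = n * voxvol
    filled = ndimage.binary_fill_holes(ind)
    filled_volume = float(filled.sum()) * voxvol

    if surface == "mesh" and n > 1:
        area = _mesh_area(ind, sp)
    else:
        area = _voxel_face_area(ind, sp)

    pts = np.argwhere(ind) * sp
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)

    # surface voxels suffice for the diameters
    eroded = ndimage.binary_erosion(ind)
    surf_pts = np.argwhere(ind & ~eroded) * sp
    if len(surf_pts) == 0:
        surf_pts = pts
    max3d = _max_pairwise(surf_pts)
    max2d_axial = _max_pairwise(surf_pts[:, [0, 1]])  # xy plane
    max2d_coronal = _max_pairwise(surf_pts[:, [0, 2]])  # xz plane
    max2d_sagittal = _max_pairwise(surf_pts[:, [1, 2]])  # yz plane

    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    return {
        "volume": volume,
        "filled_volume": filled_volume,
        "surface_area": area,
        "surface_to_volume_ratio": area / volume,
        "sphericity": float(sphericity),
        "compactness1": float(volume / (np.sqrt(np.pi) * area**1.5)),
        "compactness2": float(36.0 * np.pi * volume**2 / area**3),
        "spherical_disproportion": float(area / (4.0 * np.pi * r_equiv**2)),
        "major_axis_length": float(major),
        "minor_axis_length": float(minor),
        "least_axis_length": float(least),
        "elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
        "max_3d_diameter": max3d,
        "max_2d_diameter_axial": max2d_axial,
        "max_2d_diameter_coronal": max2d_coronal,
        "max_2d_diameter_sagittal": max2d_sagittal,
    }


# ---------------------------------------------------------------------------
# Texture matrices
# ---------------------------------------------------------------------------

def glcm_matrix(q: QuantizedROI, offset: int = 1) -> np.ndarray:
    """Symmetric GLCM merged over the 13 directions (hence all 26 offsets)."""
    lv = q.levels
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.float64)
    for d in DIRECTIONS_13:
        dd = tuple(c * offset for c in d)
        src = tuple(slice(max(0, -o), lv.shape[ax] - max(0, o)) for ax, o in enumerate(dd))
        dst = tuple(slice(max(0, o), lv.shape[ax] + min(0, o)) for ax, o in enumerate(dd))
        a = lv[src]
        b = lv[dst]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        pair = (a[valid].astype(np.int64) - 1) * ng + (b[valid] - 1)
        counts += np.bincount(pair, minlength=ng * ng).reshape(ng, ng)
    return counts + counts.T


def glrlm_matrix(q: QuantizedROI) -> np.ndarray:
    """Run-length matrix (levels x run length) merged over 13 directions."""
    lv = q.levels
    shape = lv.shape
    ng = q.n_levels
    max_run = max(shape)
    mat = np.zeros((ng, max_run), dtype=np.float64)
    i, j, k = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    flat = lv.ravel()
    big = 4 * (max(shape) + 1)
    for d in DIRECTIONS_13:
        di, dj, dk = d
        t = i if di != 0 else (j if dj != 0 else k)
        key = ((i - t * di) + big) * big * big + ((j - t * dj) + big) * big + ((k - t * dk) + big)
        order = np.lexsort((t, key))
        lv_s = flat[order]
        key_s = key[order]
        # run boundaries: line change or level change
        brk = np.empty(lv_s.size, dtype=bool)
        brk[0] = True
        brk[1:] = (key_s[1:] != key_s[:-1]) | (lv_s[1:] != lv_s[:-1])
        starts = np.nonzero(brk)[0]
        lengths = np.diff(np.append(starts, lv_s.size))
        run_levels = lv_s[starts]
        keep = run_levels > 0
        np.add.at(mat, (run_levels[keep] - 1, lengths[keep] - 1), 1.0)
    return mat


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Size-zone matrix (levels x zone size), zones 26-connected."""
    lv = q.levels
    ng = q.n_levels
    structure = np.ones((3, 3, 3), dtype=bool)
    rows = []
    for level in range(1, ng + 1):
        labeled, nzones = ndimage.label(lv == level, structure=structure)
        if nzones == 0:
            rows.append(np.zeros(0, dtype=np.int64))
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        rows.append(sizes)
    max_size = max((r.max() if r.size else 0) for r in rows)
    mat = np.zeros((ng, max(int(max_size), 1)), dtype=np.float64)
    for level, sizes in enumerate(rows):
        for s in sizes:
            mat[level, s - 1] += 1.0
    return mat


def _neighbor_sums(lv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum of in-mask 26-neighbor levels and neighbor counts per voxel."""
    padded = np.pad(lv, 1)
    nsum = np.zeros(lv.shape, dtype=np.float64)
    ncnt = np.zeros(lv.shape, dtype=np.float64)
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for a, b, c in offsets:
        sl = tuple(slice(1 + o, 1 + o + n) for o, n in zip((a, b, c), lv.shape))
        nb = padded[sl]
        inmask = nb > 0
        nsum += nb * inmask
        ncnt += inmask
    return nsum, ncnt


def ngtdm_table(q: QuantizedROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NGTDM components: for each level i, (n_i, p_i, s_i).

    s_i sums |i - mean neighbor level| over in-mask voxels of level i that
    have at least one in-mask 26-neighbor; isolated voxels are excluded.
    """
    lv = q.levels
    nsum, ncnt = _neighbor_sums(lv)
    valid = (lv > 0) & (ncnt > 0)
    levels = lv[valid].astype(np.float64)
    mean_nb = nsum[valid] / ncnt[valid]
    ng = q.n_levels
    n_i = np.bincount(lv[valid] - 1, minlength=ng).astype(np.float64)
    s_i = np.zeros(ng)
    np.add.at(s_i, lv[valid] - 1, np.abs(levels - mean_nb))
    p_i = n_i / n_i.sum() if n_i.sum() > 0 else n_i
    return n_i, p_i, s_i


def ngldm_matrix(q: QuantizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence matrix (levels x dependence count j = k + 1).

    k counts in-mask 26-neighbors whose level differs from the center by at
    most ``alpha``; missing neighbors are simply not counted.
    """
    lv = q.levels
    padded = np.pad(lv, 1)
    dep = np.zeros(lv.shape, dtype=np.int64)
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for a, b, c in offsets:
        sl = tuple(slice(1 + o, 1 + o + n) for o, n in zip((a, b, c), lv.shape))
        nb = padded[sl]
        dep += ((nb > 0) & (np.abs(nb - lv) <= alpha)).astype(np.int64)
    inmask = lv > 0
    ng = q.n_levels
    mat = np.zeros((ng, 27), dtype=np.float64)
    np.add.at(mat, (lv[inmask] - 1, dep[inmask]), 1.0)
    return mat


# ---------------------------------------------------------------------------
# Texture features
# ---------------------------------------------------------------------------

def _glcm_features(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    total = counts.sum()
    if total == 0:
        # no voxel pairs (single-voxel ROI): the constant-ROI limit
        p = np.zeros((ng, ng))
        p[0, 0] = 1.0
    else:
        p = counts / total
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(ii - jj)
    psum = np.zeros(2 * ng - 1)  # k = i + j in 2..2ng
    pdif = np.zeros(ng)  # k = |i - j| in 0..ng-1
    for k in range(2 * ng - 1):
        psum[k] = p[ii + jj == k + 2].sum()
    for k in range(ng):
        pdif[k] = p[diff == k].sum()
    ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
    kd = np.arange(0, ng, dtype=np.float64)
    sum_avg = float((ks * psum).sum())
    diff_avg = float((kd * pdif).sum())

    hxy = _entropy_bits(p.ravel())
    hx = _entropy_bits(px)
    with np.errstate(divide="ignore"):
        log_pxpy = np.log2(np.outer(px, px), where=np.outer(px, px) > 0,
                           out=np.zeros((ng, ng)))
    hxy1 = float(-(p * log_pxpy).sum())
    pxpy = np.outer(px, px)
    hxy2 = float(-(pxpy[pxpy > 0] * np.log2(pxpy[pxpy > 0])).sum())
    first_inf = (hxy - hxy1) / hx if hx > 0 else 0.0
    second_inf = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * np.log(2) * (hxy2 - hxy)))))

    auto_corr = float((ii * jj * p).sum())
    corr = (auto_corr - mu * mu) / sigma2 if sigma2 > 1e-12 else 0.0
    off = diff > 0
    return {
        "energy": float((p**2).sum()),
        "joint_entropy": hxy,
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": float(((ii - mu) ** 2 * p).sum()),
        "contrast": float((diff**2 * p).sum()),
        "dissimilarity": float((diff * p).sum()),
        "inverse_difference": float((p / (1.0 + diff)).sum()),
        "inverse_difference_norm": float((p / (1.0 + diff / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "inverse_difference_moment_norm": float((p / (1.0 + (diff / ng) ** 2)).sum()),
        "inverse_variance": float((p[off] / diff[off] ** 2).sum()),
        "sum_average": sum_avg,
        "sum_variance": float(((ks - sum_avg) ** 2 * psum).sum()),
        "sum_entropy": _entropy_bits(psum),
        "difference_average": diff_avg,
        "difference_variance": float(((kd - diff_avg) ** 2 * pdif).sum()),
        "difference_entropy": _entropy_bits(pdif),
        "autocorrelation": auto_corr,
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "correlation": corr,
        "haralick_correlation": (
            (auto_corr - mu * mu) / sigma2 if sigma2 > 1e-12 else 0.0
        ),
        "first_info_correlation": first_inf,
        "second_info_correlation": second_inf,
    }


def _run_type_features(mat: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas over a (level x size) matrix."""
    ns = mat.sum()
    if ns == 0:
        mat = np.zeros_like(mat)
        mat[0, 0] = 1.0
        ns = 1.0
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    ii, ll = np.meshgrid(i, l, indexing="ij")
    p = mat / ns
    ri = mat.sum(axis=1)
    rl = mat.sum(axis=0)
    mu_i = float((ii * p).sum())
    mu_l = float((ll * p).sum())
    if prefix == "glrlm":
        small, large = "short_run", "long_run"
        nonunif, var_name, ent_name, pct_name = (
            "run_length_nonuniformity", "run_length_variance", "run_entropy",
            "run_percentage",
        )
        # runs merged over 13 directions: one potential run per voxel-direction
        percentage = float(ns / (n_voxels * len(DIRECTIONS_13)))
    else:
        small, large = "small_area", "large_area"
        nonunif, var_name, ent_name, pct_name = (
            "zone_size_nonuniformity", "zone_size_variance", "zone_entropy",
            "zone_percentage",
        )
        percentage = float(ns / n_voxels)
    return {
        f"{small}_emphasis": float((mat / ll**2).sum() / ns),
        f"{large}_emphasis": float((mat * ll**2).sum() / ns),
        "gray_level_nonuniformity": float((ri**2).sum() / ns),
        "gray_level_nonuniformity_norm": float((ri**2).sum() / ns**2),
        nonunif: float((rl**2).sum() / ns),
        f"{nonunif}_norm": float((rl**2).sum() / ns**2),
        pct_name: percentage,
        "low_gray_level_emphasis": float((mat / ii**2).sum() / ns),
        "high_gray_level_emphasis": float((mat * ii**2).sum() / ns),
        f"{small}_low_gray_emphasis": float((mat / (ii**2 * ll**2)).sum() / ns),
        f"{small}_high_gray_emphasis": float((mat * ii**2 / ll**2).sum() / ns),
        f"{large}_low_gray_emphasis": float((mat * ll**2 / ii**2).sum() / ns),
        f"{large}_high_gray_emphasis": float((mat * ii**2 * ll**2).sum() / ns),
        "gray_level_variance": float(((ii - mu_i) ** 2 * p).sum()),
        var_name: float(((ll - mu_l) ** 2 * p).sum()),
        ent_name: _entropy_bits(p.ravel()),
    }


def _ngtdm_features(n_i, p_i, s_i) -> dict[str, float]:
    n_total = n_i.sum()
    nz = p_i > 0
    i = np.arange(1, len(p_i) + 1, dtype=np.float64)
    ngp = int(nz.sum())
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 1e-12 else 1e6
    if ngp > 1 and n_total > 0:
        iv, jv = np.meshgrid(i[nz], i[nz], indexing="ij")
        pv, qv = np.meshgrid(p_i[nz], p_i[nz], indexing="ij")
        sv, tv = np.meshgrid(s_i[nz], s_i[nz], indexing="ij")
        contrast = float(
            (pv * qv * (iv - jv) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / n_total
        )
        denom_busy = float(np.abs(iv * pv - jv * qv).sum())
        busyness = ps / denom_busy if denom_busy > 1e-12 else 0.0
        complexity = float(
            (np.abs(iv - jv) * (pv * sv + qv * tv) / (pv + qv)).sum() / n_total
        )
        denom_str = float(s_i.sum())
        strength = (
            float(((pv + qv) * (iv - jv) ** 2).sum()) / denom_str
            if denom_str > 1e-12
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def _ngldm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    ns = mat.sum()
    if ns == 0:
        mat = np.zeros_like(mat)
        mat[0, 0] = 1.0
        ns = 1.0
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)  # dependence count k+1
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = mat / ns
    gi = mat.sum(axis=1)
    dj = mat.sum(axis=0)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    # fraction of voxels with a complete in-mask 26-neighborhood
    complete = float(mat[:, 26:].sum() / ns) if mat.shape[1] > 26 else 0.0
    return {
        "low_dependence_emphasis": float((mat / jj**2).sum() / ns),
        "high_dependence_emphasis": float((mat * jj**2).sum() / ns),
        "low_gray_count_emphasis": float((mat / ii**2).sum() / ns),
        "high_gray_count_emphasis": float((mat * ii**2).sum() / ns),
        "low_dependence_low_gray_emphasis": float((mat / (ii**2 * jj**2)).sum() / ns),
        "low_dependence_high_gray_emphasis": float((mat * ii**2 / jj**2).sum() / ns),
        "high_dependence_low_gray_emphasis": float((mat * jj**2 / ii**2).sum() / ns),
        "high_dependence_high_gray_emphasis": float((mat * ii**2 * jj**2).sum() / ns),
        "gray_level_nonuniformity": float((gi**2).sum() / ns),
        "gray_level_nonuniformity_norm": float((gi**2).sum() / ns**2),
        "dependence_count_nonuniformity": float((dj**2).sum() / ns),
        "dependence_count_nonuniformity_norm": float((dj**2).sum() / ns**2),
        "dependence_count_percentage": complete,
        "gray_level_variance": float(((ii - mu_i) ** 2 * p).sum()),
        "dependence_count_variance": float(((jj - mu_j) ** 2 * p).sum()),
        "dependence_count_entropy": _entropy_bits(p.ravel()),
        "dependence_count_energy": float((p**2).sum()),
    }


def texture_features(
    q: QuantizedROI, family: str, offset: int = 1
) -> dict[str, float]:
    """Texture features for one family: GLCM (26), GLRLM (16), GLSZM (16)
    or NGTDM_NGLDM (5 + 17 = 22, prefixed ``ngtdm_``/``ngldm_``)."""
    n_vox = q.voxel_count
    if family == "GLCM":
        return {f"glcm_{k}": v for k, v in _glcm_features(glcm_matrix(q, offset)).items()}
    if family == "GLRLM":
        return {
            f"glrlm_{k}": v
            for k, v in _run_type_features(glrlm_matrix(q), n_vox, "glrlm").items()
        }
    if family == "GLSZM":
        return {
            f"glszm_{k}": v
            for k, v in _run_type_features(glszm_matrix(q), n_vox, "glszm").items()
        }
    if family == "NGTDM_NGLDM":
        out = {f"ngtdm_{k}": v for k, v in _ngtdm_features(*ngtdm_table(q)).items()}
        out.update(
            {f"ngldm_{k}": v for k, v in _ngldm_features(ngldm_matrix(q), n_vox).items()}
        )
        return out
    raise ValueError(f"unknown texture family {family!r}")


# ---------------------------------------------------------------------------
# Intensity-volume histogram
# ---------------------------------------------------------------------------

_IVH_FRACTIONS = tuple(range(10, 100, 10))


def ivh_features(vol: ImageVolume, mask: BinaryMask) -> dict[str, float]:
    """22 intensity-volume-histogram features.

    V_x: volume fraction with intensity at or above the relative intensity
    x% of the ROI range; I_x: intensity (absolute units) at volume fraction
    x% (the hottest x% of the volume); plus V10-V90, I10-I90 differences,
    the area under the V(x) curve, and the volume fraction above absolute
    intensity 0 (``v_abs_0``).
    """
    x = vol.values[mask.indicator].astype(np.float64)
    if x.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(x.min()), float(x.max())
    rng = hi - lo
    out: dict[str, float] = {}
    for f in _IVH_FRACTIONS:
        thr = lo + rng * f / 100.0
        out[f"ivh_vx{f}"] = float((x >= thr).mean())
    for f in _IVH_FRACTIONS:
        out[f"ivh_ix{f}"] = float(np.percentile(x, 100 - f))
    out["ivh_v10_minus_v90"] = out["ivh_vx10"] - out["ivh_vx90"]
    out["ivh_i10_minus_i90"] = out["ivh_ix10"] - out["ivh_ix90"]
    fine = lo + rng * np.arange(101) / 100.0
    out["ivh_auc"] = float((x[:, None] >= fine[None, :]).mean())
    out["ivh_v_abs_0"] = float((x >= 0.0).mean())
    return out


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

def build_filter_bank(
    resampled: ImageVolume, config: ExtractionConfig
) -> dict[str, ImageVolume]:
    """Compute all configured filtered images of an (already resampled) volume."""
    bank: dict[str, ImageVolume] = {}
    wavelets = None
    for f in config.filters:
        if f == "original":
            bank[f] = resampled
        elif f == "log":
            bank[f] = log_filter(resampled, config.log_sigma_mm)
        else:
            if wavelets is None:
                wavelets = wavelet_decompose(resampled, config.wavelet_family)
            bank[f] = wavelets[f]
    return bank


def extract_from_bank(
    bank: dict[str, ImageVolume], rs_mask: BinaryMask, config: ExtractionConfig
) -> pd.DataFrame:
    """Feature panel given precomputed filtered images and a resampled mask.

    Returns a long-format table (filter, feature_class, name, value) whose
    row order is fixed by the filter order and the frozen per-class lists.
    """
    if rs_mask.voxel_count == 0:
        raise ValueError("mask is empty on the resampled grid")
    rows: list[tuple[str, str, str, float]] = []

    def emit(filt: str, fclass: str, feats: dict[str, float]) -> None:
        for name, val in feats.items():
            rows.append((filt, fclass, name, float(val)))

    for filt in config.filters:
        vol = bank[filt]
        if filt == "original":
            emit(filt, "Shape", shape_features(rs_mask, config.surface_method))
        emit(filt, "FirstOrder", first_order_features(vol, rs_mask, config.bin_width))
        q = discretize(vol, rs_mask, config.bin_width)
        emit(filt, "GLCM", texture_features(q, "GLCM", config.neighborhood_offset))
        emit(filt, "GLRLM", texture_features(q, "GLRLM"))
        emit(filt, "NGTDM_NGLDM", texture_features(q, "NGTDM_NGLDM"))
        emit(filt, "GLSZM", texture_features(q, "GLSZM"))
        emit(filt, "IVH", ivh_features(vol, rs_mask))

    df = pd.DataFrame(rows, columns=["filter", "feature_class", "name", "value"])
    df["feature_id"] = df["filter"] + "/" + df["name"]
    return df


def extract_panel(
    vol: ImageVolume, mask: BinaryMask, config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Full radiomic panel of one (image, mask) pair.

    Resamples both inputs to the isotropic target spacing (sinc for the
    image, linear + threshold for the mask), applies the configured filter
    bank and computes every feature class. With the default configuration
    the result has exactly 1277 rows.
    """
    config = config or ExtractionConfig()
    if not vol.same_geometry(mask):
        raise ValueError("image and mask do not share geometry")
    if mask.voxel_count == 0:
        raise ValueError("mask is empty")
    rs_img = resample_isotropic(vol, config.target_spacing, "image")
    rs_mask = resample_isotropic(mask, config.target_spacing)
    bank = build_filter_bank(rs_img, config)
    return extract_from_bank(bank, rs_mask, config)
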
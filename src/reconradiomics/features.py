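"""Radiomic feature bank: filters, texture matrices, shape and margin features.

Feature names follow the grammar ``Family_Statistic[_Params]_Aggregation``,
e.g. ``LoG_Entropy_Sigma2.5_2D`` or ``GLCM_ASM_2D``. Aggregation modes:

* ``2D``  — computed per axial slice and averaged over mask slices, weighted
  by slice mask area (optionally largest slice only);
* ``25D`` — texture matrices accumulated in-plane across all slices, then
  summarized once;
* ``3D``  — volumetric.

Filters: Laplacian of Gaussian at configurable sigmas in mm (sigma 0 is the
identity, i.e. first-order statistics of the raw image), per-slice complex
Gabor magnitude at four orientations, and 3D separable Laws texture-energy
kernels. All convolutions use mirror boundary handling. Gray-level matrices
(GLCM, NGTDM) operate on intensities quantized to equal-width levels inside
the mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats
from scipy.optimize import curve_fit
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .io_core import ImageVolume, LesionMask

__all__ = [
    "FeatureBankConfig",
    "ParameterError",
    "QualityError",
    "UndefinedMatrixError",
    "apply_log",
    "apply_gabor",
    "apply_laws",
    "laws_code_table",
    "quantize",
    "glcm_features",
    "ngtdm_features",
    "histogram_features",
    "shape_features",
    "sigmoid_margin_features",
    "extract_features",
    "expected_feature_count",
]


class ParameterError(ValueError):
    """Invalid filter or bank parameter."""


class QualityError(RuntimeError):
    """A feature family could not be computed reliably."""


class UndefinedMatrixError(RuntimeError):
    """A texture matrix is undefined for the given mask."""


HISTOGRAM_STATS = ("Entropy", "Uniformity", "Mean", "Std", "Skewness", "Kurtosis", "Median")
Z_STATS = ("Entropy", "Uniformity")
GLCM_STATS = ("ASM", "Homogeneity", "Contrast", "Entropy", "Correlation")
NGTDM_STATS = ("Coarseness", "Contrast", "Busyness")
TEXTURE_AGGREGATIONS = ("2D", "25D", "3D")
HISTOGRAM_AGGREGATIONS = ("2D", "3D")


@dataclass(frozen=True)
class FeatureBankConfig:
    """Configurable feature grammar; the feature count is a deterministic
    function of this configuration (see :func:`expected_feature_count`)."""

    log_sigmas_mm: tuple[float, ...] = (0.0, 0.5, 1.5, 2.5)
    gabor_directions_deg: tuple[int, ...] = (0, 45, 90, 135)
    gabor_wavelengths_mm: tuple[float, ...] = (4.0,)
    laws_codes: tuple[int, ...] = (8,)
    n_gray_levels: int = 32
    n_histogram_bins: int = 32
    include_log_z: bool = True
    include_glcm: bool = True
    include_ngtdm: bool = True
    include_shape: bool = True
    include_sigmoid: bool = True
    largest_slice_only: bool = False
    sigmoid_n_profiles: int = 100
    sigmoid_profile_halflength_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ParameterError("gray-level count must be >= 2")
        if self.n_histogram_bins < 1:
            raise ParameterError("histogram bin count must be >= 1")
        if any(s < 0 for s in self.log_sigmas_mm):
            raise ParameterError("LoG sigmas must be non-negative")


#: Reduced grammar used for phantom-cohort studies: drops the sigmoid-margin
#: family, whose per-lesion cost (~100 nonlinear profile fits) dominates
#: extraction and which the desk-scale study comparisons do not require.
STUDY_CONFIG = FeatureBankConfig(include_sigmoid=False)


def _sigma_label(sigma: float) -> str:
    return f"{sigma:g}"


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _log_1d_factors(sigma_vox: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian (sum 1) and zero-sum second-derivative kernels.

    The truncated sampled second derivative of a Gaussian does not sum to
    exactly zero; the residual is folded back onto the Gaussian envelope so
    the full LoG kernel annihilates constants exactly.
    """
    radius = max(1, int(4.0 * sigma_vox + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2 * sigma_vox**2))
    g /= g.sum()
    d2 = g * (x**2 - sigma_vox**2) / sigma_vox**4
    d2 -= d2.sum() * g
    return g, d2


def apply_log(volume: ImageVolume, sigma_mm: float, mode: str = "3D") -> ImageVolume:
    """Laplacian-of-Gaussian filter; sigma 0 is the identity.

    Sigma is in mm, converted to voxels per axis using the volume spacing.
    In 2D mode the filter runs slice-wise (in-plane Laplacian); in 3D mode
    volumetrically. Separable convolution, mirror boundary; the kernel is
    zero-sum, so constant volumes map exactly to zero.
    """
    if sigma_mm < 0:
        raise ParameterError("sigma must be non-negative")
    if sigma_mm == 0:
        return volume
    values = volume.values
    if mode == "3D":
        axes = (0, 1, 2)
    elif mode == "2D":
        axes = (0, 1)
    else:
        raise ParameterError(f"unknown LoG mode {mode!r}")
    factors = {ax: _log_1d_factors(sigma_mm / volume.spacing[ax]) for ax in axes}
    out = np.zeros_like(values)
    for deriv_axis in axes:
        term = values
        for ax in axes:
            g, d2 = factors[ax]
            kernel = d2 if ax == deriv_axis else g
            term = ndimage.convolve1d(term, kernel, axis=ax, mode="mirror")
        out += term
    return ImageVolume(values=out, spacing=volume.spacing, origin=volume.origin)


def _gabor_kernel(direction_deg: float, wavelength_mm: float, spacing_xy: tuple[float, float]) -> np.ndarray:
    """Complex in-plane Gabor kernel with exact zero DC (offset invariance)."""
    sigma_mm = wavelength_mm / 2.0
    hx = max(1, int(math.ceil(3 * sigma_mm / spacing_xy[0])))
    hy = max(1, int(math.ceil(3 * sigma_mm / spacing_xy[1])))
    x = (np.arange(-hx, hx + 1) * spacing_xy[0])[:, None]
    y = (np.arange(-hy, hy + 1) * spacing_xy[1])[None, :]
    theta = math.radians(direction_deg)
    u = x * math.cos(theta) + y * math.sin(theta)
    envelope = np.exp(-(x**2 + y**2) / (2 * sigma_mm**2))
    kernel = envelope * np.exp(2j * math.pi * u / wavelength_mm)
    # remove the DC component while preserving locality
    kernel = kernel - envelope * (kernel.sum() / envelope.sum())
    return kernel


def apply_gabor(volume: ImageVolume, direction_deg: float, wavelength_mm: float) -> ImageVolume:
    """Per-slice complex Gabor magnitude at an in-plane orientation.

    The kernel modulation runs along ``(cos d, sin d)`` in the (x, y) plane;
    its envelope sigma is wavelength / 2. The kernel has exactly zero DC, so
    the magnitude is invariant to constant intensity offsets.
    """
    if direction_deg not in (0, 45, 90, 135):
        raise ParameterError(f"unsupported Gabor direction {direction_deg!r}")
    if wavelength_mm <= 0:
        raise ParameterError("wavelength must be positive")
    kernel = _gabor_kernel(direction_deg, wavelength_mm, volume.spacing[:2])
    hx, hy = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(volume.values, ((hx, hx), (hy, hy), (0, 0)), mode="reflect")
    response = signal.fftconvolve(
        padded.astype(np.complex128), kernel[:, :, None], mode="same", axes=(0, 1)
    )
    magnitude = np.abs(response[hx:-hx, hy:-hy, :])
    return ImageVolume(values=magnitude, spacing=volume.spacing, origin=volume.origin)


_LAWS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}
_LAWS_ORDER = ("L5", "E5", "S5", "R5", "W5")


def laws_code_table() -> dict[int, tuple[str, str, str]]:
    """1-based lexicographic enumeration of the 125 separable 3D Laws kernels.

    Code c (1..125) maps to the (x, y, z) kernel triple at lexicographic
    position c over (L5, E5, S5, R5, W5) in that order; e.g. code 1 = L5L5L5,
    code 8 = L5E5S5, code 125 = W5W5W5.
    """
    table = {}
    code = 1
    for a in _LAWS_ORDER:
        for b in _LAWS_ORDER:
            for c in _LAWS_ORDER:
                table[code] = (a, b, c)
                code += 1
    return table


def apply_laws(volume: ImageVolume, kernel_code: int, energy: bool = True) -> ImageVolume:
    """3D separable Laws filter; optionally followed by the local energy step
    (mean absolute response in a 5-voxel window). Mirror boundary."""
    table = laws_code_table()
    if kernel_code not in table:
        raise ParameterError(f"unknown Laws kernel code {kernel_code!r} (1..125)")
    out = volume.values
    for axis, name in enumerate(table[kernel_code]):
        out = ndimage.convolve1d(out, _LAWS_1D[name], axis=axis, mode="mirror")
    if energy:
        out = ndimage.uniform_filter(np.abs(out), size=5, mode="mirror")
    return ImageVolume(values=out, spacing=volume.spacing, origin=volume.origin)


# ---------------------------------------------------------------------------
# Quantization and histogram statistics
# ---------------------------------------------------------------------------

def quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantization of a sample to integer levels 1..n_levels.

    Bins span [min, max] of the sample; a constant sample maps to level 1;
    the maximum maps to level n_levels.
    """
    if n_levels < 2:
        raise ParameterError("n_levels must be >= 2")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot quantize an empty sample")
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64)
    levels = np.floor((values - vmin) / (vmax - vmin) * n_levels).astype(np.int64) + 1
    return np.clip(levels, 1, n_levels)


def histogram_features(values: np.ndarray, n_bins: int) -> dict[str, float]:
    """First-order statistics of a scalar sample.

    Entropy and Uniformity come from an equal-width histogram over
    [min, max]; moments are computed on the raw values. Kurtosis is the
    non-excess (Pearson) form; skewness and kurtosis of a constant sample
    are defined as 0.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        p = np.zeros(n_bins)
        p[0] = 1.0
    else:
        counts, _ = np.histogram(values, bins=n_bins, range=(vmin, vmax))
        p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())
    centered = values - values.mean()
    m2 = float((centered**2).mean())
    std = math.sqrt(m2)
    if std == 0:
        skewness, kurtosis = 0.0, 0.0
    else:
        skewness = float((centered**3).mean() / m2**1.5)
        kurtosis = float((centered**4).mean() / m2**2)
    return {
        "Entropy": entropy,
        "Uniformity": uniformity,
        "Mean": float(values.mean()),
        "Std": std,
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        "Median": float(np.median(values)),
    }


def _fixed_bin_histogram_stats(values: np.ndarray, n_bins: int, lo: float, hi: float) -> dict[str, float]:
    """Entropy/Uniformity over a fixed bin range (used by the LoG "Z" variant)."""
    counts, _ = np.histogram(np.clip(values, lo, hi), bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    nz = p[p > 0]
    return {
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "Uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# Slice helpers
# ---------------------------------------------------------------------------

def _mask_slices(mask: np.ndarray, largest_only: bool) -> list[tuple[int, float]]:
    """(slice index, mask area) pairs for slices that intersect the mask."""
    areas = mask.sum(axis=(0, 1))
    idx = np.nonzero(areas)[0]
    if largest_only and idx.size:
        k = idx[np.argmax(areas[idx])]
        return [(int(k), float(areas[k]))]
    return [(int(k), float(areas[k])) for k in idx]


def _weighted_mean(stat_rows: list[dict[str, float]], weights: list[float]) -> dict[str, float]:
    w = np.asarray(weights, dtype=np.float64)
    w = w / w.sum()
    keys = stat_rows[0].keys()
    return {k: float(sum(w[i] * stat_rows[i][k] for i in range(len(stat_rows)))) for k in keys}


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

_OFFSETS_2D = ((1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0))
_OFFSETS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def _offset_pairs(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]):
    """Co-occurring (level, level) pairs inside the mask for one offset."""
    slicer_src, slicer_dst = [], []
    for d, n in zip(offset, levels.shape):
        if d >= 0:
            slicer_src.append(slice(0, n - d))
            slicer_dst.append(slice(d, n))
        else:
            slicer_src.append(slice(-d, n))
            slicer_dst.append(slice(0, n + d))
    src_ok = mask[tuple(slicer_src)] & mask[tuple(slicer_dst)]
    return levels[tuple(slicer_src)][src_ok], levels[tuple(slicer_dst)][src_ok]


def _glcm_matrix(levels: np.ndarray, mask: np.ndarray, offsets, n: int) -> np.ndarray:
    counts = np.zeros(n * n, dtype=np.float64)
    for offset in offsets:
        a, b = _offset_pairs(levels, mask, offset)
        if a.size:
            counts += np.bincount((a - 1) * n + (b - 1), minlength=n * n)
            counts += np.bincount((b - 1) * n + (a - 1), minlength=n * n)
    return counts.reshape(n, n)


def _glcm_stats(matrix: np.ndarray) -> dict[str, float]:
    total = matrix.sum()
    if total == 0:
        raise UndefinedMatrixError("no valid co-occurrence pairs in mask")
    p = matrix / total
    n = p.shape[0]
    i = np.arange(1, n + 1)[:, None]
    j = np.arange(1, n + 1)[None, :]
    asm = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    contrast = float((p * (i - j) ** 2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mui = float((np.arange(1, n + 1) * pi).sum())
    muj = float((np.arange(1, n + 1) * pj).sum())
    sdi = math.sqrt(float(((np.arange(1, n + 1) - mui) ** 2 * pi).sum()))
    sdj = math.sqrt(float(((np.arange(1, n + 1) - muj) ** 2 * pj).sum()))
    if sdi * sdj == 0:
        correlation = 1.0  # degenerate single-level matrix
    else:
        correlation = float(((i - mui) * (j - muj) * p).sum() / (sdi * sdj))
    return {
        "ASM": asm,
        "Homogeneity": homogeneity,
        "Contrast": contrast,
        "Entropy": entropy,
        "Correlation": correlation,
    }


def glcm_features(
    volume: ImageVolume,
    mask: LesionMask,
    config: FeatureBankConfig | None = None,
    mode: str = "3D",
) -> dict[str, float]:
    """Gray-level co-occurrence statistics at distance 1.

    The matrix is symmetric, normalized to sum 1, and averaged over the 4
    in-plane directions (2D / 25D) or the 13 3D directions; only voxel pairs
    fully inside the mask are counted.
    """
    config = config or FeatureBankConfig()
    mask.check_aligned(volume)
    m = mask.values
    if m.sum() < 2:
        raise UndefinedMatrixError("co-occurrence matrix undefined for a single-voxel mask")
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[m] = quantize(volume.values[m], config.n_gray_levels)
    n = config.n_gray_levels
    if mode == "3D":
        return _glcm_stats(_glcm_matrix(levels, m, _OFFSETS_3D, n))
    if mode == "25D":
        return _glcm_stats(_glcm_matrix(levels, m, _OFFSETS_2D, n))
    if mode == "2D":
        rows, weights = [], []
        for k, area in _mask_slices(m, config.largest_slice_only):
            matrix = _glcm_matrix(levels[:, :, k : k + 1], m[:, :, k : k + 1], _OFFSETS_2D, n)
            if matrix.sum() == 0:
                continue
            rows.append(_glcm_stats(matrix))
            weights.append(area)
        if not rows:
            raise UndefinedMatrixError("no slice with valid co-occurrence pairs")
        return _weighted_mean(rows, weights)
    raise ParameterError(f"unknown aggregation mode {mode!r}")


# ---------------------------------------------------------------------------
# NGTDM (Amadasun-King gray-tone difference)
# ---------------------------------------------------------------------------

def _ngtdm_accumulate(levels: np.ndarray, mask: np.ndarray, n: int, planar: bool):
    """Per-level occupancy n_i and absolute-difference sums s_i.

    Only voxels whose full neighborhood (8-connected in-plane, or
    26-connected in 3D) lies inside the mask contribute.
    """
    if planar:
        kernel = np.ones((3, 3, 1))
        kernel[1, 1, 0] = 0.0
    else:
        kernel = np.ones((3, 3, 3))
        kernel[1, 1, 1] = 0.0
    required = int(kernel.sum())
    mf = mask.astype(np.float64)
    neighbor_count = ndimage.convolve(mf, kernel, mode="constant", cval=0.0)
    neighbor_sum = ndimage.convolve(levels * mf, kernel, mode="constant", cval=0.0)
    valid = mask & (np.round(neighbor_count) == required)
    if not valid.any():
        return None
    lv = levels[valid]
    diff = np.abs(lv - neighbor_sum[valid] / required)
    n_i = np.bincount(lv - 1, minlength=n).astype(np.float64)
    s_i = np.bincount(lv - 1, weights=diff, minlength=n)
    return n_i, s_i


def _ngtdm_stats(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    total = n_i.sum()
    p = n_i / total
    occupied = np.nonzero(p)[0]
    levels = occupied + 1
    eps = 1e-12
    psum = float((p[occupied] * s_i[occupied]).sum())
    coarseness = min(1.0 / (eps + psum), 1e12)
    ng = occupied.size
    if ng > 1:
        li = levels[:, None]
        lj = levels[None, :]
        pi = p[occupied][:, None]
        pj = p[occupied][None, :]
        contrast = float((pi * pj * (li - lj) ** 2).sum() / (ng * (ng - 1)) * (s_i.sum() / total))
    else:
        contrast = 0.0
    denom = 0.0
    for a in occupied:
        for b in occupied:
            denom += abs((a + 1) * p[a] - (b + 1) * p[b])
    busyness = psum / denom if denom > 0 else 0.0
    return {"Coarseness": coarseness, "Contrast": contrast, "Busyness": busyness}


def ngtdm_features(
    volume: ImageVolume,
    mask: LesionMask,
    config: FeatureBankConfig | None = None,
    mode: str = "3D",
) -> dict[str, float]:
    """Neighborhood gray-tone difference statistics (Coarseness, Contrast,
    Busyness) in the Amadasun-King formulation."""
    config = config or FeatureBankConfig()
    mask.check_aligned(volume)
    m = mask.values
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[m] = quantize(volume.values[m], config.n_gray_levels)
    n = config.n_gray_levels
    if mode == "3D":
        acc = _ngtdm_accumulate(levels, m, n, planar=False)
        if acc is None:
            raise UndefinedMatrixError("no voxel with a complete 26-neighborhood in mask")
        return _ngtdm_stats(*acc)
    if mode == "25D":
        acc = _ngtdm_accumulate(levels, m, n, planar=True)
        if acc is None:
            raise UndefinedMatrixError("no voxel with a complete in-plane neighborhood in mask")
        return _ngtdm_stats(*acc)
    if mode == "2D":
        rows, weights = [], []
        for k, area in _mask_slices(m, config.largest_slice_only):
            acc = _ngtdm_accumulate(
                levels[:, :, k : k + 1], m[:, :, k : k + 1], n, planar=True
            )
            if acc is None:
                continue
            rows.append(_ngtdm_stats(*acc))
            weights.append(area)
        if not rows:
            raise UndefinedMatrixError("no slice with a complete in-plane neighborhood")
        return _weighted_mean(rows, weights)
    raise ParameterError(f"unknown aggregation mode {mode!r}")


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def _surface_mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    # light smoothing before meshing: marching cubes on the raw binary grid
    # produces a stair-stepped surface whose area is biased high
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 2), sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return verts, faces

def _largest_diameter(points_mm: np.ndarray) -> float:
    if len(points_mm) < 2:
        return 0.0
    try:
        hull = ConvexHull(points_mm)
        pts = points_mm[hull.vertices]
    except QhullError:  # degenerate (flat) point sets
        pts = points_mm
    if len(pts) > 1500:
        pts = pts[:: len(pts) // 1500 + 1]
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def _shape_index_histogram(mask: np.ndarray, spacing, n_bins: int = 9) -> np.ndarray:
    """Histogram of the curvature shape index over the lesion surface.

    The index SI = (2/pi) arctan((k2 + k1) / (k2 - k1)) in [-1, 1] is
    computed from the principal curvatures of the implicit surface of the
    Gaussian-smoothed mask, sampled at mask boundary voxels.
    """
    f = ndimage.gaussian_filter(mask.astype(np.float64), sigma=1.5, mode="constant")
    gx, gy, gz = np.gradient(f, *spacing)
    gxx, gxy, gxz = np.gradient(gx, *spacing)
    _, gyy, gyz = np.gradient(gy, *spacing)
    _, _, gzz = np.gradient(gz, *spacing)
    boundary = mask & ~ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1))
    si_values = []
    bx, by, bz = np.nonzero(boundary)
    g = np.stack([gx[bx, by, bz], gy[bx, by, bz], gz[bx, by, bz]], axis=1)
    H = np.empty((len(bx), 3, 3))
    H[:, 0, 0] = gxx[bx, by, bz]
    H[:, 0, 1] = H[:, 1, 0] = gxy[bx, by, bz]
    H[:, 0, 2] = H[:, 2, 0] = gxz[bx, by, bz]
    H[:, 1, 1] = gyy[bx, by, bz]
    H[:, 1, 2] = H[:, 2, 1] = gyz[bx, by, bz]
    H[:, 2, 2] = gzz[bx, by, bz]
    norm = np.sqrt((g**2).sum(axis=1))
    ok = norm > 1e-8
    g, H, norm = g[ok], H[ok], norm[ok]
    gHg = np.einsum("ni,nij,nj->n", g, H, g)
    trace = np.einsum("nii->n", H)
    mean_curv = (gHg - norm**2 * trace) / (2 * norm**3)
    # Gaussian curvature via the adjugate of the Hessian
    adj = np.linalg.inv(H + 1e-12 * np.eye(3)) * np.linalg.det(H + 1e-12 * np.eye(3))[:, None, None]
    gauss_curv = np.einsum("ni,nij,nj->n", g, adj, g) / norm**4
    disc = np.sqrt(np.maximum(mean_curv**2 - gauss_curv, 0.0))
    k1 = mean_curv - disc
    k2 = mean_curv + disc
    denom = k2 - k1
    si = np.where(
        denom > 1e-12,
        (2.0 / math.pi) * np.arctan2(k2 + k1, denom),
        np.sign(k2 + k1),
    )
    si_values = np.clip(si, -1.0, 1.0)
    counts, _ = np.histogram(si_values, bins=n_bins, range=(-1.0, 1.0))
    total = counts.sum()
    if total == 0:
        return np.zeros(n_bins)
    return counts / total


def shape_features(mask: LesionMask, spacing=None) -> dict[str, float]:
    """Size and shape descriptors of the lesion mask.

    Volume is voxel count x voxel volume; LargestDiameter the maximum
    pairwise surface-voxel distance; Compactness = 36 pi V^2 / S^3 and
    Roundness = pi^(1/3) (6V)^(2/3) / S (both 1 for a perfect sphere) with
    S the marching-cubes surface area; SI1..SI9 the shape-index histogram.
    """
    spacing = tuple(spacing) if spacing is not None else mask.spacing
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    voxel_volume = float(np.prod(spacing))
    volume = float(m.sum()) * voxel_volume

    boundary = m & ~ndimage.binary_erosion(m, ndimage.generate_binary_structure(3, 1))
    points = np.argwhere(boundary) * np.asarray(spacing)
    diameter = _largest_diameter(points)

    try:
        verts, faces = _surface_mesh(m, spacing)
        surface_area = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        surface_area = float("nan")
    if surface_area and np.isfinite(surface_area) and surface_area > 0:
        compactness = 36.0 * math.pi * volume**2 / surface_area**3
        roundness = math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area
    else:
        compactness = roundness = 0.0

    out = {
        "Volume_3D": volume,
        "LargestDiameter_3D": diameter,
        "Compactness_3D": compactness,
        "Roundness_3D": roundness,
    }
    si = _shape_index_histogram(m, spacing)
    for k in range(9):
        out[f"Shape_SI{k + 1}_3D"] = float(si[k])
    return out


# ---------------------------------------------------------------------------
# Sigmoid margin
# ---------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _sigmoid(t, b, a, s, t0):
    return b + a / (1.0 + np.exp(np.clip(-s * (t - t0), -60, 60)))


def sigmoid_margin_features(
    volume: ImageVolume,
    mask: LesionMask,
    config: FeatureBankConfig | None = None,
) -> dict[str, float]:
    """Margin sharpness from sigmoid fits of radial intensity profiles.

    Profiles run outward from the mask centroid along quasi-uniform
    (Fibonacci-sphere) directions, centered on the surface crossing and
    spanning +- the configured half-length. Each profile is fitted with
    I(t) = b + A / (1 + exp(-s (t - t0))); features are distribution
    statistics of |A| (amplitude) and |s| (slope) over the converged fits.
    Profiles whose fit fails are excluded; more than 50% failures raise a
    quality error.
    """
    config = config or FeatureBankConfig()
    mask.check_aligned(volume)
    m = mask.values
    spacing = np.asarray(volume.spacing)
    centroid_mm = np.array(ndimage.center_of_mass(m)) * spacing
    directions = _fibonacci_directions(config.sigmoid_n_profiles)
    half = config.sigmoid_profile_halflength_mm
    t_samples = np.arange(-half, half + 1e-9, 0.5)
    max_reach = float((np.asarray(volume.shape) * spacing).max())

    amplitudes, slopes, failures = [], [], 0
    step = float(min(spacing)) / 2.0
    march = np.arange(0.0, max_reach, step)
    for d in directions:
        # surface crossing: first march point outside the mask
        pts = centroid_mm[None, :] + march[:, None] * d[None, :]
        idx = (pts / spacing).T
        inside = ndimage.map_coordinates(
            m.astype(np.float64), idx, order=1, mode="constant", cval=0.0
        ) >= 0.5
        if not inside[0]:
            failures += 1
            continue
        outside = np.nonzero(~inside)[0]
        if outside.size == 0:
            failures += 1
            continue
        t_surface = march[outside[0]]
        prof_pts = centroid_mm[None, :] + (t_surface + t_samples)[:, None] * d[None, :]
        intensities = ndimage.map_coordinates(
            volume.values, (prof_pts / spacing).T, order=1, mode="nearest"
        )
        span = float(intensities.max() - intensities.min())
        b0 = float(np.mean(intensities[-3:]))
        a0 = float(np.mean(intensities[:3]) - b0)
        try:
            popt, _ = curve_fit(
                _sigmoid,
                t_samples,
                intensities,
                p0=(b0, a0, -2.0, 0.0),
                maxfev=400,
            )
        except (RuntimeError, ValueError):
            failures += 1
            continue
        _, a, s, _ = popt
        if not np.isfinite([a, s]).all() or abs(s) > 100 or abs(a) > 10 * max(span, 1e-9):
            failures += 1
            continue
        amplitudes.append(abs(a))
        slopes.append(abs(s))

    n = config.sigmoid_n_profiles
    if failures > 0.5 * n or not amplitudes:
        raise QualityError(
            f"sigmoid margin fit failed on {failures}/{n} profiles"
        )
    amp = np.asarray(amplitudes)
    slp = np.asarray(slopes)

    def _stats3(x: np.ndarray) -> tuple[float, float, float]:
        std = float(x.std())
        kurt = float(stats.kurtosis(x, fisher=False)) if std > 0 else 0.0
        return float(x.mean()), std, kurt

    am, asd, ak = _stats3(amp)
    sm, ssd, sk = _stats3(slp)
    return {
        "Sigmoid_Amplitude_Mean_3D": am,
        "Sigmoid_Amplitude_Std_3D": asd,
        "Sigmoid_Amplitude_Kurtosis_3D": ak,
        "Sigmoid_Slope_Mean_3D": sm,
        "Sigmoid_Slope_Std_3D": ssd,
        "Sigmoid_Slope_Kurtosis_3D": sk,
    }


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def _masked_histogram_family(
    prefix: str,
    filtered_2d: ImageVolume,
    filtered_3d: ImageVolume,
    mask: np.ndarray,
    config: FeatureBankConfig,
    with_z: bool = False,
) -> dict[str, float]:
    """Histogram statistics of a filtered volume, in 2D and 3D aggregation."""
    out: dict[str, float] = {}
    values_3d = filtered_3d.values[mask]
    stats_3d = histogram_features(values_3d, config.n_histogram_bins)

    rows, weights = [], []
    for k, area in _mask_slices(mask, config.largest_slice_only):
        sl = filtered_2d.values[:, :, k][mask[:, :, k]]
        rows.append(histogram_features(sl, config.n_histogram_bins))
        weights.append(area)
    stats_2d = _weighted_mean(rows, weights)

    for stat in HISTOGRAM_STATS:
        out[f"{prefix}_{stat}_2D"] = stats_2d[stat]
    for stat in HISTOGRAM_STATS:
        out[f"{prefix}_{stat}_3D"] = stats_3d[stat]

    if with_z:
        z_prefix = prefix.replace("LoG_", "LoG_Z_", 1)
        for agg, filtered in (("2D", filtered_2d), ("3D", filtered_3d)):
            vals = filtered.values[mask]
            sd = vals.std()
            zvals = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
            zstats = _fixed_bin_histogram_stats(zvals, config.n_histogram_bins, -4.0, 4.0)
            for stat in Z_STATS:
                out[f"{z_prefix}_{stat}_{agg}"] = zstats[stat]
    return out


def extract_features(
    volume: ImageVolume,
    mask: LesionMask,
    config: FeatureBankConfig | None = None,
) -> dict[str, float]:
    """Compute the full configured feature bank for one lesion.

    Returns an ordered mapping feature name -> finite scalar; any non-finite
    feature aborts with the offending name. The number of features is a
    deterministic function of the configuration
    (:func:`expected_feature_count`).
    """
    config = config or FeatureBankConfig()
    mask.check_aligned(volume)
    m = mask.values
    out: dict[str, float] = {}

    for sigma in config.log_sigmas_mm:
        prefix = f"LoG_Sigma{_sigma_label(sigma)}"
        f2 = apply_log(volume, sigma, mode="2D")
        f3 = apply_log(volume, sigma, mode="3D")
        fam = _masked_histogram_family(
            prefix, f2, f3, m, config, with_z=config.include_log_z
        )
        # canonical grammar places the statistic before the sigma:
        # LoG_Entropy_Sigma2.5_2D
        out.update(_rename_log(fam, sigma))

    for wavelength in config.gabor_wavelengths_mm:
        for direction in config.gabor_directions_deg:
            response = apply_gabor(volume, direction, wavelength)
            tag = f"dir{direction}" + (
                f"_W{wavelength:g}" if len(config.gabor_wavelengths_mm) > 1 else ""
            )
            fam = _masked_histogram_family(
                f"Gabor_{tag}", response, response, m, config, with_z=False
            )
            for name, value in fam.items():
                stat_agg = name[len(f"Gabor_{tag}_"):]
                stat, agg = stat_agg.rsplit("_", 1)
                out[f"Gabor_{stat}_{tag}_{agg}"] = value

    for code in config.laws_codes:
        energy = apply_laws(volume, code, energy=True)
        vals = energy.values[m]
        hstats = histogram_features(vals, config.n_histogram_bins)
        for stat in HISTOGRAM_STATS:
            out[f"Laws_{stat}_{code}_3D"] = hstats[stat]

    if config.include_glcm:
        for agg in TEXTURE_AGGREGATIONS:
            gstats = glcm_features(volume, mask, config, mode=agg)
            for stat in GLCM_STATS:
                out[f"GLCM_{stat}_{agg}"] = gstats[stat]

    if config.include_ngtdm:
        for agg in TEXTURE_AGGREGATIONS:
            tstats = ngtdm_features(volume, mask, config, mode=agg)
            for stat in NGTDM_STATS:
                out[f"GTDM_{stat}_{agg}"] = tstats[stat]

    if config.include_shape:
        out.update(shape_features(mask))

    if config.include_sigmoid:
        out.update(sigmoid_margin_features(volume, mask, config))

    for name, value in out.items():
        if not np.isfinite(value):
            raise QualityError(f"feature {name!r} is non-finite")
    return out


def _rename_log(fam: dict[str, float], sigma: float) -> dict[str, float]:
    """Rewrite LoG_Sigma<r>_<Stat>_<agg> into LoG_<Stat>_Sigma<r>_<agg>."""
    label = _sigma_label(sigma)
    renamed = {}
    for name, value in fam.items():
        parts = name.split("_")
        agg = parts[-1]
        if parts[1] == f"Sigma{label}":
            stat = "_".join(parts[2:-1])
            renamed[f"LoG_{stat}_Sigma{label}_{agg}"] = value
        elif parts[0] == "LoG" and parts[1] == "Z":
            stat = "_".join(parts[3:-1])
            renamed[f"LoG_Z_{stat}_Sigma{label}_{agg}"] = value
        else:
            renamed[name] = value
    return renamed


def expected_feature_count(config: FeatureBankConfig | None = None) -> int:
    """Closed-form feature count implied by a bank configuration."""
    config = config or FeatureBankConfig()
    n = 0
    n_hist = len(HISTOGRAM_STATS) * len(HISTOGRAM_AGGREGATIONS)
    n += len(config.log_sigmas_mm) * n_hist
    if config.include_log_z:
        n += len(config.log_sigmas_mm) * len(Z_STATS) * len(HISTOGRAM_AGGREGATIONS)
    n += len(config.gabor_wavelengths_mm) * len(config.gabor_directions_deg) * n_hist
    n += len(config.laws_codes) * len(HISTOGRAM_STATS)
    if config.include_glcm:
        n += len(GLCM_STATS) * len(TEXTURE_AGGREGATIONS)
    if config.include_ngtdm:
        n += len(NGTDM_STATS) * len(TEXTURE_AGGREGATIONS)
    if config.include_shape:
        n += 4 + 9
    if config.include_sigmoid:
        n += 6
    return n
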
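"""Synthetic CT lesion phantoms rendered under four reconstruction settings.

The generator emulates the study design of a cohort imaged at two slice
thicknesses (Thin 1 mm / Thick 5 mm) crossed with two convolution kernels
(Sharp / Smooth), plus same-lesion test-retest pairs for reproducibility
analysis.

Each ground-truth scene is an ellipsoidal soft-tissue lesion with a smooth
margin placed in a uniform low-intensity background on a fine isotropic grid
(default 0.5 mm). Intra-lesion texture is a tanh-saturated Gaussian random
field (smoothed white noise passed through a saturating nonlinearity, which
forms regionally coherent intensity plateaus) whose amplitude and
correlation length depend on the class label: mutant lesions carry
higher-amplitude, shorter-correlation-length texture (heterogeneous,
multi-modal), wild-type lesions lower-amplitude, longer-correlation-length
texture. Per-lesion amplitudes and correlation lengths are lognormal around
the class medians, so the classes overlap. Lesion size and mean intensity
are drawn from the same distribution in both classes, so size is a
non-discriminative nuisance.

Reconstruction: the thin stack averages the fine grid down to 1 mm slices;
the thick stack averages non-overlapping 5-slice slabs of the thin stack
(partial-volume effect). The smooth kernel is an in-plane Gaussian blur with
low-amplitude noise; the sharp kernel an in-plane unsharp mask with
higher-amplitude noise — reproducing the kernels' noise-resolution trade-off
qualitatively, not their MTFs.
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import ndimage

from .io_core import (
    CohortManifest,
    ImageVolume,
    LesionMask,
    ManifestEntry,
    write_manifest,
    write_volume,
)

__all__ = [
    "Thickness",
    "Kernel",
    "ReconstructionSetting",
    "SETTINGS",
    "PhantomParams",
    "GroundTruthScene",
    "TestRetestPair",
    "generate_scene",
    "reconstruct",
    "generate_cohort",
    "generate_cohort_arrays",
    "generate_test_retest",
]


class Thickness(str, enum.Enum):
    THIN = "Thin"  # 1 mm
    THICK = "Thick"  # 5 mm

    @property
    def mm(self) -> float:
        return 1.0 if self is Thickness.THIN else 5.0


class Kernel(str, enum.Enum):
    SHARP = "Shp"
    SMOOTH = "Smo"


@dataclass(frozen=True)
class ReconstructionSetting:
    thickness: Thickness
    kernel: Kernel

    @property
    def name(self) -> str:
        return f"{self.thickness.value}-{self.kernel.value}"

    @staticmethod
    def from_name(name: str) -> "ReconstructionSetting":
        for s in SETTINGS:
            if s.name == name:
                return s
        raise ValueError(f"unknown reconstruction setting {name!r}")


#: The four settings of the study, in canonical order.
SETTINGS: tuple[ReconstructionSetting, ...] = (
    ReconstructionSetting(Thickness.THIN, Kernel.SHARP),
    ReconstructionSetting(Thickness.THIN, Kernel.SMOOTH),
    ReconstructionSetting(Thickness.THICK, Kernel.SHARP),
    ReconstructionSetting(Thickness.THICK, Kernel.SMOOTH),
)


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters; defaults define the package's study conditions.

    Intensities are HU-like. Texture fields are smoothed white noise
    normalized to unit variance then scaled by the class amplitude;
    ``*_corr_mm`` is the Gaussian smoothing sigma, i.e. the correlation
    length of the field.
    """

    spacing_mm: float = 0.5
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    lesion_diameter_mm: float = 16.0
    diameter_jitter_mm: float = 2.0  # uniform +- jitter, class-independent
    axis_ratio_jitter: float = 0.12  # relative jitter of ellipsoid semi-axes
    texture_saturation: float = 2.0  # tanh saturation of the random field
    background_hu: float = -800.0
    lesion_hu: float = 40.0
    margin_softness_mm: float = 1.0
    # class-dependent intra-lesion texture (the only class effect); per-lesion
    # values are lognormal around the class median so the classes overlap
    wild_amplitude_hu: float = 40.0
    wild_corr_mm: float = 3.5
    mutant_amplitude_hu: float = 70.0
    mutant_corr_mm: float = 1.5
    amplitude_spread_ln: float = 0.5  # lognormal sigma of per-lesion amplitude
    corr_spread_ln: float = 0.5  # lognormal sigma of per-lesion correlation length
    # reconstruction emulation
    thin_mm: float = 1.0
    thick_mm: float = 5.0
    smooth_sigma_mm: float = 1.6
    sharp_sigma_mm: float = 1.0
    sharp_amount: float = 0.8
    noise_smooth_hu: float = 3.0
    noise_sharp_hu: float = 14.0
    # test-retest perturbations
    retest_shift_voxels: float = 0.5
    retest_morph_prob: float = 0.25


@dataclass(frozen=True)
class GroundTruthScene:
    hires_volume: ImageVolume
    mask: LesionMask
    label: int
    params: PhantomParams
    seed: int


@dataclass(frozen=True)
class TestRetestPair:
    first: tuple[ImageVolume, LesionMask]
    second: tuple[ImageVolume, LesionMask]
    setting: ReconstructionSetting


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def _smoothed_field(rng: np.random.Generator, shape, corr_voxels: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    fieldv = ndimage.gaussian_filter(white, sigma=corr_voxels, mode="wrap")
    sd = fieldv.std()
    if sd == 0:
        return np.zeros(shape)
    return fieldv / sd


def generate_scene(label: int, params: PhantomParams | None = None, seed: int = 0) -> GroundTruthScene:
    """Generate one ground-truth lesion scene at fine isotropic spacing.

    The class label (1 = mutant, 0 = wild-type) affects only the intra-lesion
    texture regime; geometry and mean intensity distributions are identical.
    """
    params = params or PhantomParams()
    if label not in (0, 1):
        raise ValueError("label must be 0 (wild-type) or 1 (mutant)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, label, 101]))
    h = params.spacing_mm
    shape = tuple(params.grid_shape)
    extent = np.array(shape) * h

    diameter = params.lesion_diameter_mm + params.diameter_jitter_mm * rng.uniform(-1, 1)
    # mild anisotropy, same distribution in both classes; renormalized so the
    # geometric-mean diameter is preserved
    ratios = 1.0 + params.axis_ratio_jitter * rng.uniform(-1, 1, size=3)
    ratios /= np.prod(ratios) ** (1.0 / 3.0)
    semi_axes = 0.5 * diameter * ratios
    if np.any(2 * semi_axes >= extent):
        raise ValueError(
            f"lesion (diameters {2 * semi_axes} mm) does not fit the grid ({extent} mm)"
        )

    center = extent / 2.0
    coords = [(np.arange(n) + 0.5) * h - c for n, c in zip(shape, center)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    # normalized ellipsoidal radius; 1 at the surface
    r = np.sqrt(
        (xx / semi_axes[0]) ** 2 + (yy / semi_axes[1]) ** 2 + (zz / semi_axes[2]) ** 2
    )
    # approximate signed distance to the surface (mm), for a softness that is
    # metric rather than relative
    mean_axis = float(np.exp(np.mean(np.log(semi_axes))))
    signed_dist = (r - 1.0) * mean_axis
    window = 1.0 / (1.0 + np.exp(signed_dist / max(params.margin_softness_mm, 1e-6)))

    if label == 1:
        amplitude, corr = params.mutant_amplitude_hu, params.mutant_corr_mm
    else:
        amplitude, corr = params.wild_amplitude_hu, params.wild_corr_mm
    amplitude = amplitude * math.exp(params.amplitude_spread_ln * rng.standard_normal())
    corr = corr * math.exp(params.corr_spread_ln * rng.standard_normal())
    fieldv = _smoothed_field(rng, shape, corr / h)
    sat = params.texture_saturation
    if sat > 0:
        # saturating the field forms regionally coherent intensity plateaus
        # (multi-modal intra-lesion structure, like enhancing vs necrotic
        # subregions) instead of a purely Gaussian intensity spread
        fieldv = np.tanh(sat * fieldv) / math.tanh(sat)
    texture = amplitude * fieldv

    values = params.background_hu + (params.lesion_hu - params.background_hu + texture) * window
    volume = ImageVolume(values=values, spacing=(h, h, h))
    mask = LesionMask(values=r <= 1.0, spacing=(h, h, h))
    return GroundTruthScene(hires_volume=volume, mask=mask, label=int(label), params=params, seed=int(seed))


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def _slab_average(values: np.ndarray, factor: int) -> np.ndarray:
    """Average non-overlapping slabs of `factor` slices along z."""
    nz = (values.shape[2] // factor) * factor
    v = values[:, :, :nz]
    return v.reshape(v.shape[0], v.shape[1], nz // factor, factor).mean(axis=3)


def _slab_majority(mask: np.ndarray, factor: int) -> np.ndarray:
    nz = (mask.shape[0 + 2] // factor) * factor
    m = mask[:, :, :nz].astype(np.float64)
    frac = m.reshape(m.shape[0], m.shape[1], nz // factor, factor).mean(axis=3)
    return frac > 0.5


def reconstruct(
    scene: GroundTruthScene,
    setting: ReconstructionSetting,
    noise_seed: int = 0,
    add_noise: bool = True,
) -> tuple[ImageVolume, LesionMask]:
    """Render a scene under one reconstruction setting.

    Thin resamples the fine stack to 1 mm slices; Thick averages
    non-overlapping 5-slice slabs of the thin stack. Smooth applies an
    in-plane Gaussian blur and low-amplitude noise; Sharp an in-plane
    unsharp mask and higher-amplitude noise. The mask follows the same grid
    by per-voxel majority vote.
    """
    if not isinstance(setting, ReconstructionSetting):
        raise ValueError(f"unknown setting {setting!r}")
    p = scene.params
    h = p.spacing_mm
    thin_factor = int(round(p.thin_mm / h))
    if abs(thin_factor * h - p.thin_mm) > 1e-9 or thin_factor < 1:
        raise ValueError("scene z-spacing must divide the thin slice thickness")
    if scene.hires_volume.shape[2] % thin_factor:
        raise ValueError("scene z-extent must divide into thin slices")

    values = _slab_average(scene.hires_volume.values, thin_factor)
    mask = _slab_majority(scene.mask.values, thin_factor)
    z_mm = p.thin_mm
    if setting.thickness is Thickness.THICK:
        slab = int(round(p.thick_mm / p.thin_mm))
        values = _slab_average(values, slab)
        mask = _slab_majority(mask, slab)
        z_mm = p.thick_mm

    sigma_vox = (
        (p.smooth_sigma_mm if setting.kernel is Kernel.SMOOTH else p.sharp_sigma_mm) / h
    )
    if setting.kernel is Kernel.SMOOTH:
        values = ndimage.gaussian_filter(values, sigma=(sigma_vox, sigma_vox, 0), mode="mirror")
        noise_sd = p.noise_smooth_hu
    else:
        blurred = ndimage.gaussian_filter(values, sigma=(sigma_vox, sigma_vox, 0), mode="mirror")
        values = values + p.sharp_amount * (values - blurred)
        noise_sd = p.noise_sharp_hu

    if add_noise and noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(noise_seed), SETTINGS.index(setting), 202])
        )
        values = values + noise_sd * rng.standard_normal(values.shape)

    volume = ImageVolume(values=values, spacing=(h, h, z_mm))
    lesion = LesionMask(values=mask, spacing=(h, h, z_mm))
    return volume, lesion


# ---------------------------------------------------------------------------
# Cohorts and test-retest pairs
# ---------------------------------------------------------------------------

def _cohort_labels(n: int, prevalence: float) -> np.ndarray:
    if n < 4:
        raise ValueError("cohort size must be at least 4")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be strictly between 0 and 1")
    n_mut = int(round(n * prevalence))
    labels = np.zeros(n, dtype=int)
    labels[:n_mut] = 1
    return labels


def generate_cohort_arrays(
    n: int,
    prevalence: float,
    params: PhantomParams | None = None,
    seed: int = 0,
):
    """In-memory cohort: yields (patient_id, label, {setting name: (volume, mask)})."""
    params = params or PhantomParams()
    labels = _cohort_labels(n, prevalence)
    for i in range(n):
        scene_seed = int(np.random.SeedSequence([int(seed), i, 303]).generate_state(1)[0] % (2**31))
        scene = generate_scene(int(labels[i]), params, seed=scene_seed)
        rendered = {
            s.name: reconstruct(scene, s, noise_seed=scene_seed) for s in SETTINGS
        }
        yield f"P{i:03d}", int(labels[i]), rendered


def generate_cohort(
    n: int,
    prevalence: float,
    params: PhantomParams | None = None,
    seed: int = 0,
    out_dir: str = ".",
) -> CohortManifest:
    """Render a full synthetic cohort to NRRD files plus a manifest CSV.

    Every patient is rendered under all four settings; exactly
    ``round(n * prevalence)`` patients are mutants; byte-identical output
    under the same seed.
    """
    params = params or PhantomParams()
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for pid, label, rendered in generate_cohort_arrays(n, prevalence, params, seed):
        volumes, masks = {}, {}
        for sname, (volume, mask) in rendered.items():
            vpath = os.path.join(out_dir, f"{pid}_{sname}_volume.nrrd")
            mpath = os.path.join(out_dir, f"{pid}_{sname}_mask.nrrd")
            write_volume(volume, vpath)
            write_volume(mask, mpath)
            volumes[sname] = os.path.basename(vpath)
            masks[sname] = os.path.basename(mpath)
        entries.append(ManifestEntry(patient_id=pid, label=label, volumes=volumes, masks=masks))
    manifest = CohortManifest(entries=entries)
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest


def generate_test_retest(
    scene: GroundTruthScene,
    setting: ReconstructionSetting,
    seed: int = 0,
    perturb: bool = True,
) -> TestRetestPair:
    """Simulate two same-day scans of one lesion under one setting.

    The second member differs by a fresh noise realization, a sub-voxel
    rigid shift of the scene, and (with configurable probability) a one-voxel
    erosion or dilation of the mask — emulating repositioning and minor
    re-segmentation between repeat scans.
    """
    p = scene.params
    first = reconstruct(scene, setting, noise_seed=seed, add_noise=perturb)
    if not perturb:
        return TestRetestPair(first=first, second=first, setting=setting)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    shift = rng.uniform(-p.retest_shift_voxels, p.retest_shift_voxels, size=3)
    shifted_values = ndimage.shift(scene.hires_volume.values, shift, order=1, mode="nearest")
    shifted_mask = ndimage.shift(scene.mask.values.astype(np.float64), shift, order=1, mode="nearest") > 0.5
    if rng.uniform() < p.retest_morph_prob:
        structure = ndimage.generate_binary_structure(3, 1)
        if rng.uniform() < 0.5:
            shifted_mask = ndimage.binary_erosion(shifted_mask, structure)
        else:
            shifted_mask = ndimage.binary_dilation(shifted_mask, structure)
    shifted_scene = GroundTruthScene(
        hires_volume=ImageVolume(values=shifted_values, spacing=scene.hires_volume.spacing),
        mask=LesionMask(values=shifted_mask, spacing=scene.mask.spacing),
        label=scene.label,
        params=p,
        seed=scene.seed,
    )
    second = reconstruct(shifted_scene, setting, noise_seed=int(seed) + 1, add_noise=True)
    return TestRetestPair(first=first, second=second, setting=setting)


def params_to_dict(params: PhantomParams) -> dict:
    return asdict(params)


def params_from_dict(d: dict) -> PhantomParams:
    base = PhantomParams()
    known = {k: v for k, v in d.items() if k in asdict(base)}
    if "grid_shape" in known:
        known["grid_shape"] = tuple(known["grid_shape"])
    return replace(base, **known)
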
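"""Synthetic co-registered CT / ventilation / lung-mask phantoms.

The generator emulates the statistical structure that CT-to-ventilation
translation relies on: lung parenchyma whose attenuation (HU) varies
smoothly around an emphysema-free mean, spatially coherent defect regions
shifted toward low attenuation, a gravity-dependent ventral-to-dorsal
ventilation gradient, and SPECT-like degradation (resolution blur plus
multiplicative log-normal noise).

Ventilation truth is a smooth, strictly monotone sigmoid of local HU —
well-aerated parenchyma near −820 HU ventilates highly, emphysematous
tissue below about −900 HU barely at all — multiplied by the gravity
gradient.  This is a learnable monotone surrogate, not a physical
air-content model.

All randomness flows from a single seeded generator per call; identical
parameters and seed give bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import VolumeGrid

__all__ = ["PhantomParams", "generate_phantom", "generate_cohort", "ventilation_from_hu"]

#: sigmoid midpoint / width (HU) of the HU → ventilation link; with these
#: values every voxel below the −856 HU emphysema threshold falls below
#: the ventilation of the parenchyma bulk (≈ −820 HU).
_VENT_HU_MID = -860.0
_VENT_HU_WIDTH = 22.0


@dataclass
class PhantomParams:
    """Parameters of one synthetic lung phantom.

    Spatial sizes are in mm so that the same anatomy can be rendered at
    any grid resolution.  ``coupling`` interpolates between ventilation
    that ignores HU entirely (0) and the pure monotone HU link (1).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    lung_axes: tuple[float, float, float] = (30.0, 16.0, 11.0)  # semi-axes, mm (z, y, x)
    parenchyma_hu_mean: float = -820.0
    parenchyma_hu_sd: float = 40.0
    hu_correlation_mm: float = 5.0
    defect_count: int = 4
    defect_radius_range: tuple[float, float] = (4.0, 9.0)
    defect_hu_shift: float = -90.0
    gravity_gradient: float = 0.2
    noise_sd: float = 0.3
    blur_fwhm_vox: float = 2.5
    coupling: float = 1.0
    background_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.defect_count < 0:
            raise ValueError("defect_count must be >= 0")
        if min(self.defect_radius_range) <= 0:
            raise ValueError("defect radii must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.noise_sd < 0 or self.blur_fwhm_vox < 0:
            raise ValueError("noise_sd and blur_fwhm_vox must be >= 0")


def ventilation_from_hu(hu: np.ndarray, coupling: float = 1.0) -> np.ndarray:
    """Strictly monotone sigmoid link between attenuation and ventilation.

    Increasing in HU over the parenchymal range: ≈0.86 at −820 HU
    (healthy parenchyma), 0.5 at −860 HU, ≈0.14 at −900 HU — tissue
    pushed toward very low attenuation is emphysematous and poorly
    ventilated, which is exactly what the −856 HU CT surrogate encodes.
    """
    v = 1.0 / (1.0 + np.exp(-(np.asarray(hu, dtype=float) - _VENT_HU_MID) / _VENT_HU_WIDTH))
    return (1.0 - coupling) + coupling * v


def _smooth_field(shape, sd, correlation_vox, rng) -> np.ndarray:
    """Zero-mean Gaussian random field with unit-calibrated SD after smoothing."""
    white = rng.standard_normal(shape)
    if correlation_vox <= 0:
        return sd * white
    f = ndimage.gaussian_filter(white, sigma=correlation_vox, mode="wrap")
    s = f.std()
    return sd * f / s if s > 0 else f


def _two_lung_mask(params: PhantomParams) -> np.ndarray:
    shape = params.grid_shape
    spacing = np.asarray(params.spacing)
    extent = (np.asarray(shape) - 1) * spacing  # mm span of voxel centers
    zc = 0.5 * extent[0]
    yc = 0.5 * extent[1]
    # left/right lung centers offset along x
    ax = np.asarray(params.lung_axes)
    gap = 0.25 * ax[2]
    centers = [
        (zc, yc, 0.5 * extent[2] - ax[2] - gap),
        (zc, yc, 0.5 * extent[2] + ax[2] + gap),
    ]
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    mask = np.zeros(shape, dtype=np.uint8)
    for cz, cy, cx in centers:
        if (
            cz - ax[0] < 0 or cz + ax[0] > extent[0]
            or cy - ax[1] < 0 or cy + ax[1] > extent[1]
            or cx - ax[2] < 0 or cx + ax[2] > extent[2]
        ):
            raise ValueError("lung ellipsoids exceed the grid; shrink lung_axes or enlarge grid")
        r2 = ((zz - cz) / ax[0]) ** 2 + ((yy - cy) / ax[1]) ** 2 + ((xx - cx) / ax[2]) ** 2
        mask[r2 <= 1.0] = 1
    return mask


def generate_phantom(
    params: PhantomParams,
) -> tuple[VolumeGrid, VolumeGrid, VolumeGrid, VolumeGrid]:
    """Generate one phantom.

    Returns
    -------
    (ct_raw, vent_raw, lung_mask, vent_truth)
        ``ct_raw`` in HU (soft-tissue background, parenchyma field with
        defect shifts inside the lung); ``vent_raw`` the noisy, blurred
        SPECT-like observation; ``lung_mask`` binary; ``vent_truth`` the
        noise-free ventilation used as evaluation ground truth.  All share
        the grid; ventilation volumes are 0 outside the lung.
    """
    rng = np.random.default_rng(params.seed)
    mask = _two_lung_mask(params)
    shape = params.grid_shape
    spacing = np.asarray(params.spacing)

    corr_vox = params.hu_correlation_mm / float(np.mean(spacing))
    hu = params.parenchyma_hu_mean + _smooth_field(
        shape, params.parenchyma_hu_sd, corr_vox, rng
    )

    # spatially coherent defects: spherical HU shifts toward emphysema
    lung_idx = np.argwhere(mask == 1)
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    defect_label = np.zeros(shape, dtype=np.uint8)
    for _ in range(params.defect_count):
        center = lung_idx[rng.integers(len(lung_idx))] * spacing
        radius = rng.uniform(*params.defect_radius_range)
        d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        inside = d2 <= radius**2
        # smooth edge so defects are coherent but not binary-sharp in HU
        w = np.exp(-0.5 * d2 / max(radius / 2.0, 1e-9) ** 2)
        hu = hu + params.defect_hu_shift * np.where(inside, 1.0, w * (d2 <= (1.8 * radius) ** 2))
        defect_label[inside & (mask == 1)] = 1

    ct = np.where(mask == 1, hu, params.background_hu)

    gravity = 1.0 + params.gravity_gradient * (
        np.arange(shape[1])[None, :, None] / max(shape[1] - 1, 1) - 0.5
    )
    vent_truth = ventilation_from_hu(ct, params.coupling) * gravity
    vent_truth = np.where(mask == 1, vent_truth, 0.0)

    vent = vent_truth
    if params.blur_fwhm_vox > 0:
        # mask-normalized blur: SPECT-like resolution loss inside the lung
        # without bleeding counts into the zero background (whose shell
        # would otherwise dominate a desk-scale lung)
        sigma = params.blur_fwhm_vox / 2.3548
        num = ndimage.gaussian_filter(vent, sigma=sigma)
        den = ndimage.gaussian_filter(mask.astype(float), sigma=sigma)
        vent = np.where(mask == 1, num / np.maximum(den, 1e-9), 0.0)
    if params.noise_sd > 0:
        noise = np.exp(rng.normal(-0.5 * params.noise_sd**2, params.noise_sd, shape))
        vent = vent * noise
    # arbitrary relative-count scale, as from a SPECT console
    vent = np.where(mask == 1, 100.0 * vent, 0.0)

    sp = tuple(params.spacing)
    make = lambda d: VolumeGrid(data=d, spacing=sp)  # noqa: E731
    out = (make(ct), make(vent), make(mask), make(np.where(mask == 1, vent_truth, 0.0)))
    out[0].defect_label = defect_label  # ground-truth defect voxels, for evaluation
    return out


@dataclass
class CohortCase:
    """One raw phantom case with identity metadata."""

    case_id: str
    group_id: str
    ct: VolumeGrid
    vent: VolumeGrid
    lung_mask: VolumeGrid
    vent_truth: VolumeGrid
    params: PhantomParams = field(repr=False, default=None)


def generate_cohort(
    n: int,
    params: PhantomParams | None = None,
    seed: int = 0,
    paired_fraction: float = 0.05,
) -> list[CohortCase]:
    """Generate ``n`` phantom cases with per-case anatomical jitter.

    Lung size and defect count vary between cases.  A fraction of cases
    come in pairs sharing a ``group_id`` — emulating initial and
    follow-up scans of the same patient, which must never be split
    across folds or across the train/test boundary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    n_pairs = int(round(paired_fraction * n / 2.0))
    cases: list[CohortCase] = []
    group = 0
    i = 0
    while i < n:
        group += 1
        scans = 2 if (n_pairs > 0 and i + 1 < n) else 1
        if scans == 2:
            n_pairs -= 1
        base_axes = np.asarray(params.lung_axes) * rng.uniform(0.9, 1.1, size=3)
        base_defects = int(rng.integers(max(params.defect_count - 2, 0), params.defect_count + 3))
        for s in range(scans):
            axes = tuple(base_axes * rng.uniform(0.98, 1.02, size=3))
            p = replace(
                params,
                lung_axes=axes,
                defect_count=base_defects,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            ct, vent, mask, truth = generate_phantom(p)
            cases.append(
                CohortCase(
                    case_id=f"case{i:03d}",
                    group_id=f"g{group:03d}",
                    ct=ct,
                    vent=vent,
                    lung_mask=mask,
                    vent_truth=truth,
                    params=p,
                )
            )
            i += 1
    return cases
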
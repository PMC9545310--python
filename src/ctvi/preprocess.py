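"""Preprocessing: raw CT / ventilation / mask volumes → fixed-grid model tensors.

The pipeline mirrors standard practice for CT-to-SPECT translation
training data: (optional externally computed rigid transform) → resample
to a common isotropic spacing → crop or pad about the lung centroid →
linear CT rescaling / median ventilation normalization → masking to the
whole-lung volume.

CT values are rescaled affinely with the anchors −999 HU → 0 and
−250 HU → 1, preserving the ordering of attenuation values (absolute HU
carry physiologic meaning, e.g. the −856 HU emphysema threshold).
Ventilation images are relative-intensity data prone to outliers, so they
are normalized by the in-lung *median* rather than the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml
from scipy import ndimage

from .volumes import PairedCase, VolumeGrid, apply_mask

__all__ = [
    "PreprocessConfig",
    "resample",
    "crop_or_pad",
    "rescale_ct",
    "normalize_spect",
    "spect_lung_mask",
    "preprocess_case",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing pipeline.

    Defaults are the full-scale values (2.5 mm isotropic grid of 128³
    voxels); tests and desk-scale experiments use smaller ``target_shape``.
    """

    target_spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    target_shape: tuple[int, int, int] = (128, 128, 128)
    ct_hu_lo: float = -999.0  # HU mapped to 0
    ct_hu_hi: float = -250.0  # HU mapped to 1
    spect_mask_fraction: float = 0.15
    interpolation: dict = field(
        default_factory=lambda: {"image": "linear", "mask": "nearest"}
    )

    def __post_init__(self) -> None:
        self.target_spacing = tuple(float(s) for s in self.target_spacing)
        self.target_shape = tuple(int(s) for s in self.target_shape)
        if self.ct_hu_lo >= self.ct_hu_hi:
            raise ValueError("ct_hu_lo must be < ct_hu_hi")
        if not 0.0 < self.spect_mask_fraction < 1.0:
            raise ValueError("spect_mask_fraction must lie in (0, 1)")
        if any(s <= 0 for s in self.target_spacing) or any(s <= 0 for s in self.target_shape):
            raise ValueError("target_spacing and target_shape must be strictly positive")

    def to_yaml(self, path) -> None:
        d = {
            "target_spacing": list(self.target_spacing),
            "target_shape": list(self.target_shape),
            "ct_hu_lo": self.ct_hu_lo,
            "ct_hu_hi": self.ct_hu_hi,
            "spect_mask_fraction": self.spect_mask_fraction,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def resample(
    vol: VolumeGrid,
    target_spacing: float | tuple[float, float, float],
    mode: Literal["linear", "nearest"] = "linear",
) -> VolumeGrid:
    """Resample to ``target_spacing`` (mm); shape = round(shape·spacing/target).

    ``linear`` is used for images, ``nearest`` for masks (preserves
    binarity).  Grid extents are kept aligned (voxel-center convention).
    """
    if np.isscalar(target_spacing):
        target_spacing = (float(target_spacing),) * 3
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    order = {"linear": 1, "nearest": 0}[mode]
    zoom = [s / t for s, t in zip(vol.spacing, target_spacing)]
    if all(abs(z - 1.0) < 1e-12 for z in zoom):
        return vol.copy()
    data = ndimage.zoom(
        np.asarray(vol.data, dtype=float), zoom, order=order, mode="nearest", grid_mode=True
    )
    if mode == "nearest":
        data = data.astype(vol.data.dtype, copy=False)
    # grid_mode keeps the overall extent; voxel centers shift by half the
    # spacing difference.
    origin = tuple(
        o + 0.5 * (t - s) for o, s, t in zip(vol.origin, vol.spacing, target_spacing)
    )
    return VolumeGrid(data=data, spacing=target_spacing, origin=origin)


def mask_centroid(mask: VolumeGrid) -> tuple[int, int, int]:
    """Voxel-index centroid of a binary mask, rounded to the nearest voxel.

    Half-integer ties break toward the lower index.
    """
    idx = np.nonzero(mask.data)
    if idx[0].size == 0:
        raise ValueError("mask is empty")
    # ceil(c - 0.5) rounds .5 down, otherwise to nearest
    return tuple(int(np.ceil(np.mean(ax) - 0.5)) for ax in idx)


def crop_or_pad(
    vol: VolumeGrid,
    target_shape: tuple[int, int, int],
    center: tuple[int, int, int] | None = None,
    lung_mask: VolumeGrid | None = None,
) -> VolumeGrid:
    """Crop and/or zero-pad ``vol`` to ``target_shape`` about ``center``.

    When ``center`` is ``None`` the volume center is used.  If
    ``lung_mask`` is given, the window is shifted minimally so that it
    covers the whole lung whenever the lung's bounding box fits in
    ``target_shape``; lung voxels that still fall outside are counted and
    reported with a warning.  Passing the same ``center`` and
    ``lung_mask`` for every volume of a case guarantees an identical
    window for all of them.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise ValueError("target_shape must be strictly positive")
    if center is None:
        center = tuple(s // 2 for s in vol.shape)
    starts = [int(c) - t // 2 for c, t in zip(center, target_shape)]
    if lung_mask is not None and lung_mask.shape != vol.shape:
        raise ValueError("lung_mask must share the volume's grid")
    if lung_mask is not None and np.count_nonzero(lung_mask.data):
        nz = np.nonzero(lung_mask.data)
        for ax, (st, t) in enumerate(zip(starts, target_shape)):
            lo, hi = int(nz[ax].min()), int(nz[ax].max())
            if hi - lo + 1 <= t:  # lung fits: force the window over it
                starts[ax] = min(max(st, hi + 1 - t), lo)
    # Shift the window back inside the volume where possible so that
    # off-center lungs are not needlessly truncated.
    starts = [
        min(max(st, 0), max(sh - t, 0)) if sh >= t else st
        for st, sh, t in zip(starts, vol.shape, target_shape)
    ]
    out = np.zeros(target_shape, dtype=vol.data.dtype)
    src, dst = [], []
    for st, sh, t in zip(starts, vol.shape, target_shape):
        lo = max(st, 0)
        hi = min(st + t, sh)
        src.append(slice(lo, hi))
        dst.append(slice(lo - st, hi - st))
    out[tuple(dst)] = vol.data[tuple(src)]
    if lung_mask is not None:
        total = int(np.count_nonzero(lung_mask.data))
        kept = int(np.count_nonzero(lung_mask.data[tuple(src)]))
        if kept < total:
            warnings.warn(
                f"crop window truncates the lung: {total - kept} of {total} "
                "lung voxels lost",
                stacklevel=2,
            )
    origin = tuple(o + st * s for o, st, s in zip(vol.origin, starts, vol.spacing))
    return VolumeGrid(data=out, spacing=vol.spacing, origin=origin)


def rescale_ct(hu: VolumeGrid, cfg: PreprocessConfig | None = None) -> VolumeGrid:
    """Linearly rescale CT so that −999 HU → 0 and −250 HU → 1.

    Values below the lower anchor are clipped to 0.  Values above 1
    (soft tissue, vessels) are *kept*: the rescale exists to preserve the
    ordering of attenuation values, and an upper clip would destroy the
    ordering among denser voxels.  The map is affine and monotone
    non-decreasing on [ct_hu_lo, ∞).
    """
    cfg = cfg or PreprocessConfig()
    out = (np.asarray(hu.data, dtype=float) - cfg.ct_hu_lo) / (cfg.ct_hu_hi - cfg.ct_hu_lo)
    np.clip(out, 0.0, None, out=out)
    return hu.with_data(out)


def normalize_spect(vent: VolumeGrid, lung_mask: VolumeGrid) -> VolumeGrid:
    """Divide the ventilation volume by its in-lung median.

    The median (rather than the mean) is robust to the local intensity
    outliers typical of SPECT counts.  Post-condition: the median of the
    output over the lung mask is exactly 1.

    Raises
    ------
    ValueError
        If the mask is empty or the in-lung median is not positive
        (a signal of corrupt ventilation data).
    """
    if vent.shape != lung_mask.shape:
        raise ValueError("ventilation and lung mask shapes differ")
    inside = lung_mask.data == 1
    if not inside.any():
        raise ValueError("lung mask is empty")
    med = float(np.median(np.asarray(vent.data, dtype=float)[inside]))
    if med <= 0:
        raise ValueError(f"in-lung ventilation median must be positive, got {med}")
    return vent.with_data(np.asarray(vent.data, dtype=float) / med)


def spect_lung_mask(vent: VolumeGrid, fraction: float = 0.15) -> VolumeGrid:
    """Threshold a ventilation image at ``fraction`` of its maximum.

    Produces the SPECT-derived lung mask used to quantify CT/SPECT
    registration quality (Dice overlap against the CT-derived mask).
    """
    data = np.asarray(vent.data, dtype=float)
    vmax = data.max()
    if vmax <= 0:
        raise ValueError("ventilation volume has no positive voxels")
    return vent.with_data((data >= fraction * vmax).astype(np.uint8))


def preprocess_case(
    ct_raw: VolumeGrid,
    vent_raw: VolumeGrid | None,
    lung_mask_raw: VolumeGrid,
    cfg: PreprocessConfig | None = None,
    case_id: str = "case",
    group_id: str | None = None,
    rigid_transform=None,
) -> PairedCase:
    """Run the full preprocessing pipeline for one case.

    Order of operations: optional rigid transform (a callable
    ``VolumeGrid -> VolumeGrid`` computed externally; default identity) →
    resample to ``cfg.target_spacing`` → crop/pad to ``cfg.target_shape``
    about the lung-mask centroid → CT rescale and ventilation median
    normalization → masking to the lung.  ``vent_raw=None`` yields an
    inference-only case.
    """
    cfg = cfg or PreprocessConfig()
    if rigid_transform is not None:
        ct_raw = rigid_transform(ct_raw)
        lung_mask_raw = rigid_transform(lung_mask_raw)
        if vent_raw is not None:
            vent_raw = rigid_transform(vent_raw)

    ct = resample(ct_raw, cfg.target_spacing, mode="linear")
    mask = resample(lung_mask_raw, cfg.target_spacing, mode="nearest")
    if not np.count_nonzero(mask.data):
        raise ValueError(f"case {case_id}: lung mask empty after resampling")
    center = mask_centroid(mask)
    ct = crop_or_pad(ct, cfg.target_shape, center=center, lung_mask=mask)
    mask_c = crop_or_pad(mask, cfg.target_shape, center=center, lung_mask=mask)
    ct = apply_mask(rescale_ct(ct, cfg), mask_c)

    vent = None
    if vent_raw is not None:
        vent = resample(vent_raw, cfg.target_spacing, mode="linear")
        if vent.shape != mask.shape:
            raise ValueError(
                f"case {case_id}: ventilation grid {vent.shape} does not match the "
                f"CT grid {mask.shape} after resampling; supply a rigid transform "
                "mapping the ventilation scan onto the CT frame"
            )
        vent = crop_or_pad(vent, cfg.target_shape, center=center, lung_mask=mask)
        vent = apply_mask(normalize_spect(vent, mask_c), mask_c)

    return PairedCase(
        case_id=case_id,
        group_id=group_id if group_id is not None else case_id,
        ct=ct,
        lung_mask=mask_c,
        ventilation=vent,
    )
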
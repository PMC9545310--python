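"""Core volumetric data model and NIfTI I/O.

Every stage of the pipeline exchanges :class:`VolumeGrid` objects: a 3-D
scalar field plus voxel spacing and origin.  The in-memory axis order is
fixed as ``(z, y, x)`` — converters at the I/O boundary translate to and
from the format-native ordering.  Voxel indices are 0-based and the world
coordinate of voxel ``(i, j, k)`` is ``origin + index * spacing``
(voxel-center convention).

Value semantics depend on modality: Hounsfield units for CT, arbitrary
relative counts for ventilation, {0, 1} for masks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "PairedCase",
    "read_volume",
    "write_volume",
    "apply_mask",
]


@dataclass
class VolumeGrid:
    """A 3-D scalar field with geometry metadata.

    Parameters
    ----------
    data
        3-D array indexed ``(z, y, x)``.
    spacing
        Per-axis voxel size in mm, ordered ``(z, y, x)``; strictly positive.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = field(default="zyx", repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3-D with all axes >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.axis_order != "zyx":
            raise ValueError("internal axis order is fixed to 'zyx'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def is_binary(self) -> bool:
        """True if the grid contains only the values 0 and 1."""
        return bool(np.isin(self.data, (0, 1)).all())

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """New grid with the same geometry and different voxel values."""
        return dataclasses.replace(self, data=data)

    def copy(self) -> "VolumeGrid":
        return dataclasses.replace(self, data=self.data.copy())


@dataclass
class PairedCase:
    """Co-registered CT / ventilation / lung-mask volumes on a common grid.

    ``ventilation`` may be ``None`` for inference-only cases.  ``group_id``
    encodes patient identity: initial and follow-up scans of the same
    patient share a group and must never be split across data subsets.
    """

    case_id: str
    group_id: str
    ct: VolumeGrid
    lung_mask: VolumeGrid
    ventilation: VolumeGrid | None = None

    def __post_init__(self) -> None:
        vols = [self.ct, self.lung_mask] + ([self.ventilation] if self.ventilation else [])
        shapes = {v.shape for v in vols}
        spacings = {v.spacing for v in vols}
        if len(shapes) != 1 or len(spacings) != 1:
            raise ValueError(
                f"case {self.case_id}: ct/ventilation/lung_mask must share shape and "
                f"spacing (shapes {shapes}, spacings {spacings})"
            )
        if not self.lung_mask.is_binary():
            raise ValueError(f"case {self.case_id}: lung_mask must be binary")

    def validate_masked(self, atol: float = 0.0) -> None:
        """Check that ct and ventilation are exactly 0 outside the lung."""
        bg = self.lung_mask.data == 0
        for name, vol in (("ct", self.ct), ("ventilation", self.ventilation)):
            if vol is None:
                continue
            off = np.abs(vol.data[bg])
            if off.size and off.max() > atol:
                raise ValueError(f"case {self.case_id}: {name} nonzero outside lung mask")


def _nifti_affine(spacing_zyx, origin_zyx) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = spacing_zyx[::-1]
    affine[:3, 3] = origin_zyx[::-1]
    return affine


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI (``.nii``/``.nii.gz``) or MetaImage (``.mha``/``.mhd``) volume.

    The format-native ``(x, y, z)`` array is transposed into the package's
    ``(z, y, x)`` convention.

    Raises
    ------
    IOError
        If the file is missing or unreadable.
    ValueError
        If the image is not 3-D.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    if path.suffix.lower() in {".mha", ".mhd"}:
        return _read_metaimage(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise IOError(f"could not read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    spacing_xyz = img.header.get_zooms()[:3]
    origin_xyz = np.asarray(img.affine)[:3, 3]
    return VolumeGrid(
        data=np.ascontiguousarray(data.transpose(2, 1, 0)),
        spacing=tuple(float(s) for s in spacing_xyz[::-1]),
        origin=tuple(float(o) for o in origin_xyz[::-1]),
    )


def _read_metaimage(path: Path) -> VolumeGrid:
    try:
        import SimpleITK as sitk
    except ImportError as exc:  # pragma: no cover
        raise IOError("MetaImage support requires SimpleITK") from exc
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {img.GetDimension()}-D")
    # SimpleITK's array view is already (z, y, x); its metadata is (x, y, z).
    return VolumeGrid(
        data=sitk.GetArrayFromImage(img),
        spacing=tuple(img.GetSpacing()[::-1]),
        origin=tuple(img.GetOrigin()[::-1]),
    )


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    """Write ``vol`` as NIfTI; round-trips losslessly through :func:`read_volume`.

    Raises
    ------
    IOError
        If the parent directory does not exist or the path is unwritable.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(
        np.ascontiguousarray(vol.data.transpose(2, 1, 0)),
        _nifti_affine(vol.spacing, vol.origin),
    )
    img.header.set_zooms(vol.spacing[::-1])
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"could not write volume {path}: {exc}") from exc


def apply_mask(vol: VolumeGrid, mask: VolumeGrid) -> VolumeGrid:
    """Zero every voxel of ``vol`` outside the binary ``mask``.

    This is the masking step that restricts model inputs and outputs to the
    whole-lung volume: output equals ``vol`` where ``mask == 1`` and is
    exactly 0 elsewhere.  Idempotent.
    """
    if vol.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {vol.shape} vs mask {mask.shape}")
    if not mask.is_binary():
        raise ValueError("mask must contain only 0 and 1")
    out = np.where(mask.data == 1, vol.data, 0)
    return vol.with_data(out.astype(vol.data.dtype, copy=False))
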
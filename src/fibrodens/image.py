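"""Voxel containers and image I/O.

CT volumes are held as :class:`VoxelVolume` (Hounsfield units, float32) and
lung segmentations as :class:`LungMask` (uint8 labels: 0 background, 1 right
lung, 2 left lung).  Volumes round-trip through NIfTI-1; DICOM series can be
imported with the rescale slope/intercept applied to recover HU.

World coordinates are derived from the voxel spacing alone (axis-aligned
affine, 0-based indices); oblique acquisitions are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Standard 12-bit CT representable range in Hounsfield units.
HU_MIN = -1024.0
HU_MAX = 3071.0

RIGHT_LUNG = 1
LEFT_LUNG = 2


class ImageFormatError(ValueError):
    """Raised when a file cannot be read as a CT volume or mask."""


class GridMismatchError(ValueError):
    """Raised when a volume and mask do not share grid shape and spacing."""


@dataclass
class VoxelVolume:
    """A 3D grid of Hounsfield-unit values with physical voxel spacing.

    Parameters
    ----------
    data
        3D float array of HU values.
    spacing_mm
        Physical size of one voxel along each axis, in millimetres.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of a single voxel in cubic millimetres."""
        return float(np.prod(self.spacing_mm))


@dataclass
class LungMask:
    """Label volume co-registered with a :class:`VoxelVolume`.

    Labels: 0 = background, 1 = right lung, 2 = left lung.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> set[int]:
        return set(int(v) for v in np.unique(self.data))


def check_same_grid(volume: VoxelVolume, mask: LungMask) -> None:
    """Ensure volume and mask share grid shape and spacing."""
    if volume.shape != mask.shape:
        raise GridMismatchError(
            f"shape mismatch: volume {volume.shape} vs mask {mask.shape}"
        )
    if not np.allclose(volume.spacing_mm, mask.spacing_mm):
        raise GridMismatchError(
            f"spacing mismatch: volume {volume.spacing_mm} vs mask {mask.spacing_mm}"
        )


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_volume(volume: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a HU volume as NIfTI-1 (float32)."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing_mm))
    nib.save(img, os.fspath(path))


def write_mask(mask: LungMask, path: str | os.PathLike) -> None:
    """Write a lung mask as NIfTI-1 (uint8 labels)."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing_mm))
    nib.save(img, os.fspath(path))


def _load_nifti(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise ImageFormatError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    if data.ndim != 3:
        raise ImageFormatError(f"{path!r}: expected a 3D volume, got shape {data.shape}")
    if any(s <= 0 for s in spacing):
        raise ImageFormatError(f"{path!r}: missing or non-positive voxel spacing {spacing}")
    return data, spacing


def _load_dicom_series(dirpath: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an axial DICOM series, applying rescale slope/intercept to get HU."""
    import pydicom

    files = sorted(
        os.path.join(dirpath, f)
        for f in os.listdir(dirpath)
        if not f.startswith(".")
    )
    if not files:
        raise ImageFormatError(f"{dirpath!r}: empty DICOM series directory")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise ImageFormatError(f"cannot read DICOM file {f!r}: {exc}") from exc
        slices.append(ds)
    slices.sort(key=lambda ds: float(getattr(ds, "ImagePositionPatient", [0, 0, 0])[2])
                if hasattr(ds, "ImagePositionPatient") else float(getattr(ds, "InstanceNumber", 0)))
    first = slices[0]
    modality = str(getattr(first, "Modality", "CT"))
    if modality != "CT":
        raise ImageFormatError(f"{dirpath!r}: modality {modality!r} is not CT")
    try:
        ps = [float(v) for v in first.PixelSpacing]
    except Exception as exc:
        raise ImageFormatError(f"{dirpath!r}: missing PixelSpacing") from exc
    dz = float(getattr(first, "SliceThickness", 0) or 0)
    if len(slices) > 1 and hasattr(slices[0], "ImagePositionPatient"):
        dz = abs(float(slices[1].ImagePositionPatient[2]) -
                 float(slices[0].ImagePositionPatient[2])) or dz
    if dz <= 0 or any(p <= 0 for p in ps):
        raise ImageFormatError(f"{dirpath!r}: missing voxel spacing")
    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    # stack slices along the last axis: (row, col, slice)
    data = np.stack(planes, axis=-1)
    return data, (ps[0], ps[1], dz)


def read_volume(path: str | os.PathLike) -> VoxelVolume:
    """Read a CT volume from a NIfTI-1 file or a DICOM series directory.

    DICOM pixel data are converted to Hounsfield units via the per-slice
    rescale slope and intercept.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        data, spacing = _load_dicom_series(path)
    else:
        if not os.path.exists(path):
            raise ImageFormatError(f"no such file: {path!r}")
        data, spacing = _load_nifti(path)
    return VoxelVolume(np.asarray(data, dtype=np.float32), spacing)


def read_mask(path: str | os.PathLike) -> LungMask:
    """Read a lung label mask from a NIfTI-1 file."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ImageFormatError(f"no such file: {path!r}")
    data, spacing = _load_nifti(path)
    rounded = np.rint(data)
    if not np.array_equal(rounded, data) or rounded.min() < 0 or rounded.max() > 255:
        raise ImageFormatError(f"{path!r}: mask is not label-valued")
    return LungMask(rounded.astype(np.uint8), spacing)
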
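"""Volume and mask containers, NIfTI I/O, and intensity normalization.

All grids use the axis convention ``(slice, row, col)`` with 0-based
indices: axis 0 walks through axial slices. Spacing is the per-axis voxel
size in millimetres, in the same order. Shapes and spacings must already
agree between a volume and any mask applied to it; resampling between
mismatched grids is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    EmptyInputError,
    NotThreeDimensionalError,
    ShapeMismatchError,
    VolumeFormatError,
)

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "normalize_minmax",
    "volume_ml",
    "check_congruent",
]


def _validate_grid(data: np.ndarray, spacing: tuple[float, ...]) -> None:
    if data.ndim != 3:
        raise NotThreeDimensionalError(
            f"expected a 3D grid, got {data.ndim} dimensions"
        )
    if min(data.shape) < 1:
        raise ShapeMismatchError(f"all dimensions must be >= 1, got {data.shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ShapeMismatchError(f"spacing must be 3 positive values, got {spacing}")


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar intensity grid with voxel spacing in mm.

    Intensities are in arbitrary scanner units before normalization and
    dimensionless in [0, 1] afterwards.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        spacing = tuple(float(s) for s in self.spacing)
        _validate_grid(data, spacing)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """A 3D boolean grid congruent with a companion :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data) > 0
        spacing = tuple(float(s) for s in self.spacing)
        _validate_grid(data, spacing)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())


def check_congruent(a: ImageVolume | BinaryMask, b: ImageVolume | BinaryMask) -> None:
    """Raise :class:`ShapeMismatchError` unless shapes and spacings agree."""
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=1e-5, atol=1e-6):
        raise ShapeMismatchError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI header/data from {path}: {exc}") from exc
    if data.ndim != 3:
        raise NotThreeDimensionalError(
            f"{path} holds a {data.ndim}D image; a 3D volume is required"
        )
    spacing = tuple(float(z) for z in zooms[:3])
    return data, spacing  # type: ignore[return-value]


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI-1 image, intensities unmodified."""
    data, spacing = _load_nifti(path)
    return ImageVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a 3D NIfTI-1 image and binarize it (non-zero -> True)."""
    data, spacing = _load_nifti(path)
    return BinaryMask(data=data > 0, spacing=spacing)


def write_volume(volume: ImageVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1; masks are stored as uint8 0/1.

    Data and spacing round-trip through :func:`read_volume` /
    :func:`read_mask`.
    """
    path = Path(path)
    if isinstance(volume, BinaryMask):
        out = volume.data.astype(np.uint8)
    else:
        out = volume.data.astype(np.float32)
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(out, affine)
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"cannot write NIfTI to {path}: {exc}") from exc


def normalize_minmax(volume: ImageVolume, roi: BinaryMask | None = None) -> ImageVolume:
    """Min-max scale intensities to [0, 1].

    The scaling ``(I - min) / (max - min)`` is monotone and idempotent on
    already-normalized input. By default min/max are taken over the whole
    volume; if ``roi`` is given they are taken inside the region of
    interest only and the mapped intensities are clipped to [0, 1].

    A constant volume (max == min) cannot be scaled; it is returned as all
    zeros with a warning rather than raising, so degenerate slices do not
    abort a pipeline.
    """
    if roi is not None:
        check_congruent(volume, roi)
        if not roi.data.any():
            raise EmptyInputError("ROI is empty; cannot normalize within it")
        sample = volume.data[roi.data]
    else:
        sample = volume.data
    lo = float(sample.min())
    hi = float(sample.max())
    if hi == lo:
        warnings.warn(
            "constant-intensity volume: min == max, returning all zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        return ImageVolume(np.zeros_like(volume.data), volume.spacing)
    scaled = (volume.data - lo) / (hi - lo)
    if roi is not None:
        scaled = np.clip(scaled, 0.0, 1.0)
    return ImageVolume(scaled, volume.spacing)


def volume_ml(mask: BinaryMask) -> float:
    """Mask volume in millilitres: true-voxel count x voxel volume (mm^3) / 1000."""
    voxel_mm3 = float(np.prod(mask.spacing))
    return mask.count() * voxel_mm3 / 1000.0
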
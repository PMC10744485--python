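"""NIfTI volume I/O and mask-driven region-of-interest cropping.

The first preprocessing stage of the reconstruction pipeline: a CT and its
vertebral segmentation mask are restricted to the tight bounding box of
the labelled voxels, so downstream projection and learning operate on the
spine only.

Files are written with a diagonal affine ``diag(voxel_size) + origin``;
arrays keep the project-wide (z, y, x) index order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .types import CTVolume, SegmentationMask

__all__ = [
    "BoundingBox",
    "EmptyMaskError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mask_bounding_box",
    "crop_to_mask",
]


class EmptyMaskError(ValueError):
    """Raised when an operation requires at least one labelled voxel."""


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive voxel-index box, ordered (z, y, x)."""

    min_index: tuple[int, int, int]
    max_index: tuple[int, int, int]

    def __post_init__(self):
        if any(lo > hi for lo, hi in zip(self.min_index, self.max_index)):
            raise ValueError("BoundingBox min_index must be <= max_index")
        if any(lo < 0 for lo in self.min_index):
            raise ValueError("BoundingBox indices must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo + 1 for lo, hi in zip(self.min_index, self.max_index))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(
            slice(lo, hi + 1) for lo, hi in zip(self.min_index, self.max_index)
        )


def _affine(voxel_size, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a 3D NIfTI file into a :class:`CTVolume`."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # unreadable header or not a NIfTI
        raise IOError(f"cannot read NIfTI header from {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    aff = img.affine
    voxel_size = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    return CTVolume(data, voxel_size, origin)


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(
        np.asarray(vol.data, dtype=np.float32),
        _affine(vol.voxel_size_mm, vol.origin_mm),
    )
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, path)


def read_mask(path: str | os.PathLike) -> SegmentationMask:
    vol = read_volume(path)
    labels = np.asarray(vol.data)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded):
            raise ValueError(f"{path}: mask voxels are not integer labels")
        labels = rounded.astype(np.int32)
    return SegmentationMask(labels)


def write_mask(
    mask: SegmentationMask,
    path: str | os.PathLike,
    voxel_size=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask.labels, dtype=np.int16), _affine(voxel_size, origin)
    )
    nib.save(img, path)


def mask_bounding_box(mask: SegmentationMask) -> BoundingBox:
    """Tightest inclusive box containing every nonzero label."""
    nonzero = np.nonzero(mask.labels)
    if nonzero[0].size == 0:
        raise EmptyMaskError("mask contains no labelled voxels")
    mins = tuple(int(ax.min()) for ax in nonzero)
    maxs = tuple(int(ax.max()) for ax in nonzero)
    return BoundingBox(mins, maxs)


def crop_to_mask(
    vol: CTVolume, mask: SegmentationMask
) -> tuple[CTVolume, SegmentationMask]:
    """Crop volume and mask to the mask's bounding box (inclusive ends).

    The output origin is shifted by ``min_index * voxel_size`` so the world
    coordinate of every retained voxel is unchanged.
    """
    if vol.shape != mask.shape:
        raise ValueError(
            f"volume shape {vol.shape} does not match mask shape {mask.shape}"
        )
    box = mask_bounding_box(mask)
    sl = box.slices
    origin = tuple(
        o + lo * v
        for o, lo, v in zip(vol.origin_mm, box.min_index, vol.voxel_size_mm)
    )
    return (
        CTVolume(vol.data[sl].copy(), vol.voxel_size_mm, origin),
        SegmentationMask(mask.labels[sl].copy()),
    )
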
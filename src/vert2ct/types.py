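"""Core value types shared across the pipeline.

Axis convention, fixed project-wide: volumes are indexed (z, y, x) with
z = inferior→superior, y = posterior→anterior, x = right→left.  The
anterior radiograph is the projection along y (image rows = z, columns =
x); the lateral radiograph is acquired after rotating the viewing
direction about z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "SegmentationMask", "XRayImage", "PairedSample"]


@dataclass
class CTVolume:
    """A 3D intensity grid with voxel spacing and world origin (mm)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"CTVolume data must be 3D, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("CTVolume axes must each have length >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CTVolume intensities must be finite")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SegmentationMask:
    """Integer label grid aligned to a CTVolume; 0 = background, vertebrae
    labelled contiguously from 1."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("SegmentationMask labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("SegmentationMask labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("SegmentationMask labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class XRayImage:
    """A radiograph-like 2D image with values in [0, 1]."""

    pixels: np.ndarray
    view_angle_deg: float = 0.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("XRayImage pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("XRayImage pixels must be finite")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("XRayImage pixels must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PairedSample:
    """One training/evaluation record: normalized CT plus two radiographs."""

    ct: np.ndarray
    xray1: np.ndarray
    xray2: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        self.ct = np.asarray(self.ct, dtype=np.float64)
        self.xray1 = np.asarray(self.xray1, dtype=np.float64)
        self.xray2 = np.asarray(self.xray2, dtype=np.float64)
        if self.ct.ndim != 3:
            raise ValueError("PairedSample ct must be 3D")
        if self.ct.min() < -1e-9 or self.ct.max() > 1 + 1e-9:
            raise ValueError("PairedSample ct must lie in [0, 1]")
        for name, img in (("xray1", self.xray1), ("xray2", self.xray2)):
            if img.ndim != 2 or img.shape[0] != img.shape[1]:
                raise ValueError(f"PairedSample {name} must be square 2D")
        if self.xray1.shape != self.xray2.shape:
            raise ValueError("PairedSample views must be equal-sized")
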
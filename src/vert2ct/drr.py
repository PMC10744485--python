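"""Digitally reconstructed radiographs by parallel-ray volume compositing.

A DRR is computed in four steps: (1) rotate the volume about the
inferior–superior (z) axis to the requested view angle, (2) normalize
intensities to [0, 1] by a fixed scale, (3) cast parallel rays along the
posterior→anterior (y) axis and composite emission/opacity front-to-back
using a six-point piecewise-linear opacity transfer function, (4) min–max
rescale the ray integrals and resample to the detector size.

Parallel-beam geometry is used throughout: the desk-scale analogue of
orthographic volume-rendering captures, and the choice that admits
closed-form checks (an axis-aligned box projects to its exact footprint).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .types import CTVolume, XRayImage

__all__ = [
    "OpacityTransferFunction",
    "ProjectionGeometry",
    "default_xray_tf",
    "evaluate_tf",
    "rotate_about_z",
    "composite_rays",
    "project",
    "make_biplanar",
    "save_png",
]

# Default six-point opacity map (normalized intensity, opacity): soft tissue
# stays faint, bone dominates.  Configurable; these values are this
# package's own calibration of an X-ray-style volume-rendering preset.
_DEFAULT_POINTS = (
    (0.00, 0.00),
    (0.10, 0.00),
    (0.30, 0.02),
    (0.55, 0.10),
    (0.75, 0.35),
    (1.00, 0.85),
)


@dataclass(frozen=True)
class OpacityTransferFunction:
    """Six-point piecewise-linear map from normalized intensity to opacity."""

    control_points: tuple = _DEFAULT_POINTS

    def __post_init__(self):
        pts = tuple((float(v), float(a)) for v, a in self.control_points)
        object.__setattr__(self, "control_points", pts)
        if len(pts) != 6:
            raise ValueError("transfer function requires exactly six control points")
        vs = [v for v, _ in pts]
        if any(b <= a for a, b in zip(vs, vs[1:])):
            raise ValueError("control intensities must be strictly increasing")
        if any(not (0.0 <= a <= 1.0) for _, a in pts):
            raise ValueError("control opacities must lie in [0, 1]")

    def __call__(self, v):
        return evaluate_tf(self, v)


def default_xray_tf() -> OpacityTransferFunction:
    return OpacityTransferFunction()


def evaluate_tf(tf: OpacityTransferFunction, v) -> np.ndarray | float:
    """Piecewise-linear interpolation, clamped outside the control range."""
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("transfer function input must be finite")
    xs = np.array([p[0] for p in tf.control_points])
    ys = np.array([p[1] for p in tf.control_points])
    out = np.interp(v, xs, ys)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProjectionGeometry:
    """View angle about z (0 = anterior, 90 = lateral), detector size,
    intensity normalization divisor and ray sampling step."""

    view_angle_deg: float = 0.0
    image_size: tuple[int, int] = (128, 128)
    intensity_scale: float = 2500.0
    step_mm: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.view_angle_deg < 360.0):
            raise ValueError("view_angle_deg must lie in [0, 360)")
        if any(s < 1 for s in self.image_size):
            raise ValueError("image_size entries must be >= 1")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")


def rotate_about_z(data: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a (z, y, x) grid about z with trilinear interpolation.

    Positive angles turn the anterior view toward the lateral view; a 90°
    rotation agrees exactly with the lattice rotation ``np.rot90(data,
    k=1, axes=(1, 2))``.
    """
    angle = angle_deg % 360.0
    if angle == 0.0:
        return data
    return ndimage.rotate(
        data,
        angle,
        axes=(2, 1),
        reshape=False,
        order=1,
        mode="constant",
        cval=float(data.min()),
    )


def composite_rays(
    samples: np.ndarray, alphas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Front-to-back emission–absorption compositing along axis 0.

    ``samples``/``alphas``: (n_samples, ...) normalized emissions and
    opacities.  Returns the composited colour C and the per-step
    accumulated-opacity trajectory A (n_samples, ...); A is monotone
    nondecreasing and bounded by 1.
    """
    C = np.zeros(samples.shape[1:], dtype=np.float64)
    A = np.zeros_like(C)
    traj = np.empty_like(samples, dtype=np.float64)
    for i in range(samples.shape[0]):
        a = alphas[i]
        C += (1.0 - A) * a * samples[i]
        A += (1.0 - A) * a
        traj[i] = A
    return C, traj


def project(
    vol: CTVolume,
    tf: OpacityTransferFunction | None = None,
    geom: ProjectionGeometry | None = None,
    mode: str = "composite",
) -> XRayImage:
    """Render one DRR of ``vol`` for the given geometry.

    ``mode='composite'`` uses the emission–absorption rule (emission equal
    to normalized intensity); ``mode='attenuation'`` uses a Beer–Lambert
    style ``1 - exp(-sum(alpha))`` integral instead.  A degenerate
    (constant) ray image yields an all-zeros output with a warning.
    """
    tf = tf or default_xray_tf()
    geom = geom or ProjectionGeometry()
    if mode not in ("composite", "attenuation"):
        raise ValueError(f"unknown DRR mode {mode!r}")
    data = rotate_about_z(np.asarray(vol.data, dtype=np.float64), geom.view_angle_deg)
    v = np.clip(data / geom.intensity_scale, 0.0, 1.0)

    ny = v.shape[1]
    vy = vol.voxel_size_mm[1]
    step_vox = geom.step_mm / vy
    positions = np.arange(0.0, ny - 1 + 1e-9, step_vox)
    lo = np.floor(positions).astype(int)
    hi = np.minimum(lo + 1, ny - 1)
    frac = (positions - lo)[:, None, None]
    samples = (1.0 - frac) * v[:, lo, :].transpose(1, 0, 2) + frac * v[
        :, hi, :
    ].transpose(1, 0, 2)
    alphas = evaluate_tf(tf, samples)
    if mode == "composite":
        img, _ = composite_rays(samples, alphas)
    else:
        img = 1.0 - np.exp(-alphas.sum(axis=0) * (geom.step_mm / vy))

    mn, mx = img.min(), img.max()
    if mx - mn < 1e-12:
        warnings.warn("degenerate DRR (constant ray integrals); emitting zeros")
        img = np.zeros_like(img)
    else:
        img = (img - mn) / (mx - mn)
    if img.shape != tuple(geom.image_size):
        img = resize(img, geom.image_size, order=1, anti_aliasing=False)
        img = np.clip(img, 0.0, 1.0)
    return XRayImage(img, view_angle_deg=geom.view_angle_deg)


def make_biplanar(
    vol: CTVolume,
    tf: OpacityTransferFunction | None = None,
    lateral_angle_deg: float = 90.0,
    geom: ProjectionGeometry | None = None,
    mode: str = "composite",
) -> tuple[XRayImage, XRayImage]:
    """Anterior (0°) and lateral (``lateral_angle_deg``) DRR pair."""
    if not (0.0 < lateral_angle_deg < 180.0):
        raise ValueError("lateral_angle_deg must lie in (0, 180)")
    geom = geom or ProjectionGeometry()
    anterior = project(
        vol, tf, ProjectionGeometry(0.0, geom.image_size, geom.intensity_scale, geom.step_mm), mode
    )
    lateral = project(
        vol,
        tf,
        ProjectionGeometry(
            lateral_angle_deg, geom.image_size, geom.intensity_scale, geom.step_mm
        ),
        mode,
    )
    return anterior, lateral


def save_png(img: XRayImage, path: str | os.PathLike) -> None:
    """Write an 8-bit grayscale PNG."""
    iio.imwrite(path, (np.clip(img.pixels, 0, 1) * 255).astype(np.uint8))
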
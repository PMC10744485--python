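"""Synthetic vertebral-column CT phantoms with aligned label masks.

Each phantom is a stack of elliptic-cylinder vertebral bodies (optionally
with a posterior arch) along the inferior–superior axis: a bright cortical
shell, a medium trabecular interior, and a low-intensity surround, plus an
integer mask labelling the vertebrae 1..n.  The geometry is deliberately
simple — the elliptic cross-section (wider left–right than
anterior–posterior) and the posterior arch are the minimal features that
make the anterior and lateral projections genuinely different, which is
what a two-view fusion reconstructor must exploit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .types import CTVolume, SegmentationMask

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "DEFAULT_SPEC_RANGES"]

# depth/width anisotropy of the vertebral body cross-section
_BODY_ASPECT = 0.75
# cortical shell thickness in voxels
_SHELL_VOX = 1.5


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic spine volume.

    Lengths in mm, intensities on a Hounsfield-like [0, 2500] scale.
    ``body_radius_mm`` and ``body_height_mm`` are (low, high) ranges from
    which per-vertebra values are drawn.
    """

    n_vertebrae: int = 4
    body_radius_mm: tuple[float, float] = (8.0, 12.0)
    body_height_mm: tuple[float, float] = (8.0, 11.0)
    disc_gap_mm: float = 3.0
    arch_enabled: bool = True
    cortical_intensity: float = 1500.0
    trabecular_intensity: float = 500.0
    background_intensity: float = 50.0
    noise_sd: float = 20.0
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if not (
            self.cortical_intensity > self.trabecular_intensity > self.background_intensity
        ):
            raise ValueError(
                "intensities must satisfy cortical > trabecular > background"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("body_radius_mm", "body_height_mm"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) range")
        if self.disc_gap_mm <= 0:
            raise ValueError("disc_gap_mm must be positive")
        if any(s < 1 for s in self.volume_shape):
            raise ValueError("volume_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm entries must be positive")


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[CTVolume, SegmentationMask]:
    """Generate one phantom CT and its voxel-exact label mask.

    Deterministic given ``(spec, seed)``.  Raises ``ValueError`` naming the
    violating axis if the requested column cannot fit inside
    ``spec.volume_shape``.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.volume_shape
    vz, vy, vx = spec.voxel_size_mm

    heights = rng.uniform(*spec.body_height_mm, size=spec.n_vertebrae)
    radii = rng.uniform(*spec.body_radius_mm, size=spec.n_vertebrae)

    column_mm = heights.sum() + spec.disc_gap_mm * (spec.n_vertebrae - 1)
    if column_mm / vz > nz - 2:
        raise ValueError(
            f"vertebral column ({column_mm:.1f} mm) exceeds volume extent "
            f"along z ({nz} voxels)"
        )
    r_max = radii.max()
    # posterior reach includes the arch; the body is centred in-plane
    y_reach = r_max * _BODY_ASPECT + (0.9 * r_max if spec.arch_enabled else 0.0)
    if y_reach / vy > (ny - 1) / 2 - 1:
        raise ValueError("vertebral body exceeds volume extent along y")
    if r_max / vx > (nx - 1) / 2 - 1:
        raise ValueError("vertebral body exceeds volume extent along x")

    data = np.full(spec.volume_shape, spec.background_intensity, dtype=np.float64)
    labels = np.zeros(spec.volume_shape, dtype=np.int32)

    zz = np.arange(nz) * vz
    yy = (np.arange(ny) - (ny - 1) / 2) * vy
    xx = (np.arange(nx) - (nx - 1) / 2) * vx
    Y, X = np.meshgrid(yy, xx, indexing="ij")

    z0 = (nz * vz - column_mm) / 2
    for i in range(spec.n_vertebrae):
        h, r = heights[i], radii[i]
        z_lo, z_hi = z0, z0 + h
        z0 = z_hi + spec.disc_gap_mm
        in_z = (zz >= z_lo) & (zz < z_hi)
        if not in_z.any():
            continue
        ry, rx = r * _BODY_ASPECT, r
        body = (Y / ry) ** 2 + (X / rx) ** 2 <= 1.0
        core = (Y / max(ry - _SHELL_VOX * vy, 0.1)) ** 2 + (
            X / max(rx - _SHELL_VOX * vx, 0.1)
        ) ** 2 <= 1.0
        shell2d = body & ~core
        region = body.copy()
        arch = np.zeros_like(body)
        if spec.arch_enabled:
            # posterior arch: thin box behind the body plus a spinous stub
            arch = (
                (Y >= -ry - 0.9 * r)
                & (Y <= -0.6 * ry)
                & (np.abs(X) <= 0.35 * rx)
                & ~body
            )
            region |= arch
        z_idx = np.where(in_z)[0]
        interior_z = z_idx[1:-1] if len(z_idx) > 2 else z_idx[:0]
        endplate_z = [z_idx[0], z_idx[-1]] if len(z_idx) > 1 else [z_idx[0]]
        for zi in z_idx:
            labels[zi][region] = i + 1
            data[zi][arch] = spec.cortical_intensity
        for zi in interior_z:
            data[zi][body & core] = spec.trabecular_intensity
            data[zi][shell2d] = spec.cortical_intensity
        for zi in endplate_z:
            data[zi][body] = spec.cortical_intensity

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)

    vol = CTVolume(data, spec.voxel_size_mm)
    return vol, SegmentationMask(labels)


# worst-case column (4 bodies at 11 mm + 3 gaps at 4 mm = 56 mm) fits the
# default 64-voxel extent with margin for every possible draw
DEFAULT_SPEC_RANGES: dict = {
    "n_vertebrae": (3, 4),
    "body_radius_low_mm": (7.0, 9.0),
    "body_radius_high_mm": (10.0, 13.0),
    "disc_gap_mm": (2.5, 4.0),
}


def generate_cohort(
    n_cases: int,
    spec_ranges: dict | None = None,
    seed: int = 0,
    out_dir: str | os.PathLike = "cohort",
    base_spec: PhantomSpec | None = None,
) -> list[str]:
    """Write ``n_cases`` phantom CT+mask pairs as NIfTI files.

    One directory per case (``case_0000`` ...), each holding ``ct.nii.gz``
    and ``mask.nii.gz``.  Per-case parameters are drawn from
    ``spec_ranges`` under a stream derived from ``(seed, case index)``, so
    cohorts are reproducible case-by-case.  Returns the directories in
    creation order.
    """
    from . import volume_roi

    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        ranges.update(spec_ranges)
    base = base_spec or PhantomSpec()
    os.makedirs(out_dir, exist_ok=True)

    dirs = []
    for i in range(n_cases):
        rng = np.random.default_rng([seed, i])
        n_lo, n_hi = ranges["n_vertebrae"]
        r_lo = rng.uniform(*ranges["body_radius_low_mm"])
        r_hi = rng.uniform(*ranges["body_radius_high_mm"])
        spec = replace(
            base,
            n_vertebrae=int(rng.integers(n_lo, n_hi + 1)),
            body_radius_mm=(r_lo, max(r_hi, r_lo + 0.1)),
            disc_gap_mm=float(rng.uniform(*ranges["disc_gap_mm"])),
        )
        vol, mask = generate_phantom(spec, seed=int(rng.integers(0, 2**31 - 1)))
        case_dir = os.path.join(out_dir, f"case_{i:04d}")
        os.makedirs(case_dir, exist_ok=True)
        volume_roi.write_volume(vol, os.path.join(case_dir, "ct.nii.gz"))
        volume_roi.write_mask(
            mask,
            os.path.join(case_dir, "mask.nii.gz"),
            voxel_size=vol.voxel_size_mm,
            origin=vol.origin_mm,
        )
        dirs.append(case_dir)
    return dirs
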
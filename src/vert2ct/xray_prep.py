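"""Radiograph preprocessing, HDF5 packaging, dataset split, augmentation.

The preprocessing chain isolates the bright (bony) structure of a
synthetic radiograph: threshold, morphological clean-up, largest connected
component, tight crop, normalization, square padding and resampling to a
fixed detector size.  Paired samples are stored one-per-case in HDF5 with
datasets ``"ct"``, ``"xray1"`` and ``"xray2"``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .types import PairedSample, XRayImage

__all__ = [
    "EmptyXRayError",
    "DatasetSplit",
    "preprocess_xray",
    "package_case",
    "read_case",
    "split_cases",
    "augment",
    "resize_for_augment",
    "norm_stats",
]

AUGMENT_RESIZE = 150
FINE_SIZE = 128


class EmptyXRayError(ValueError):
    """Raised when thresholding leaves no foreground pixel."""


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=-1)  # luminance average over channels
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2D (or multi-channel 2D) image")
    return img


DEFAULT_THRESHOLD = 0.02


def preprocess_xray(
    img: np.ndarray, out_size: int = FINE_SIZE, threshold: str | float = DEFAULT_THRESHOLD
) -> XRayImage:
    """Eight-step radiograph preprocessing.

    (1) grayscale, (2) brightness threshold, (3) 3x3 opening then 5x5
    closing, (4) largest 8-connected foreground component, (5) crop to its
    bounding box, (6) min–max normalize, (7) symmetric zero-padding to
    square (extra row/column at bottom/right), (8) bilinear resample to
    ``out_size x out_size``.

    ``threshold`` is either a float — an absolute cut on the min–max
    normalized image, keeping everything brighter than that fraction of
    the dynamic range (default 0.02, i.e. crop away true black) — or
    ``"otsu"`` for a histogram-adaptive cut.  The fixed low cut is the
    default because it is stable under re-application: the chain is then
    idempotent on its own output, which an adaptive threshold (recomputed
    on the renormalized crop) cannot guarantee.
    """
    gray = _to_gray(img)
    lo, hi = gray.min(), gray.max()
    if hi - lo < 1e-12:
        mask = np.ones_like(gray, dtype=bool)
    else:
        gray = (gray - lo) / (hi - lo)
        if threshold == "otsu":
            mask = gray >= threshold_otsu(gray)
        else:
            mask = gray >= float(threshold)
    if not mask.any():
        raise EmptyXRayError("no foreground after thresholding")

    mask = morphology.opening(mask, morphology.footprint_rectangle((3, 3)))
    mask = morphology.closing(mask, morphology.footprint_rectangle((5, 5)))
    if not mask.any():
        raise EmptyXRayError("no foreground after morphological clean-up")

    labels = measure.label(mask, connectivity=2)
    regions = measure.regionprops(labels)
    # largest component; ties broken by topmost-leftmost bounding box
    best = min(regions, key=lambda r: (-r.area, r.bbox[0], r.bbox[1]))
    r0, c0, r1, c1 = best.bbox  # half-open
    crop = gray[r0:r1, c0:c1]

    lo, hi = crop.min(), crop.max()
    crop = np.zeros_like(crop) if hi - lo < 1e-12 else (crop - lo) / (hi - lo)

    h, w = crop.shape
    if h != w:
        d = abs(h - w)
        before, after = d // 2, d - d // 2
        pad = ((before, after), (0, 0)) if h < w else ((0, 0), (before, after))
        crop = np.pad(crop, pad)

    out = resize(crop, (out_size, out_size), order=1, anti_aliasing=False)
    return XRayImage(np.clip(out, 0.0, 1.0))


def package_case(
    ct,
    xray1,
    xray2,
    path: str | os.PathLike,
    intensity_scale: float = 2500.0,
) -> str:
    """Write one case to HDF5 with datasets {"ct", "xray1", "xray2"}.

    ``ct`` may be a CTVolume (denormalized intensities, divided by
    ``intensity_scale``) or an already-normalized [0, 1] array.  All three
    inputs are validated before the file is created.
    """
    from .types import CTVolume

    if ct is None or xray1 is None or xray2 is None:
        raise ValueError("package_case requires ct, xray1 and xray2")
    if isinstance(ct, CTVolume):
        ct_arr = np.clip(np.asarray(ct.data, dtype=np.float64) / intensity_scale, 0.0, 1.0)
    else:
        ct_arr = np.asarray(ct, dtype=np.float64)
    if ct_arr.ndim != 3:
        raise ValueError("ct must be 3D")
    x1 = np.asarray(getattr(xray1, "pixels", xray1), dtype=np.float64)
    x2 = np.asarray(getattr(xray2, "pixels", xray2), dtype=np.float64)
    for name, x in (("xray1", x1), ("xray2", x2)):
        if x.ndim != 2:
            raise ValueError(f"{name} must be 2D")
    with h5py.File(path, "w") as f:
        f.create_dataset("ct", data=ct_arr)
        f.create_dataset("xray1", data=x1)
        f.create_dataset("xray2", data=x2)
    return str(path)


def read_case(path: str | os.PathLike, case_id: str | None = None) -> PairedSample:
    with h5py.File(path, "r") as f:
        keys = set(f.keys())
        if keys != {"ct", "xray1", "xray2"}:
            raise ValueError(f"{path}: expected datasets ct/xray1/xray2, found {sorted(keys)}")
        return PairedSample(
            ct=f["ct"][...],
            xray1=f["xray1"][...],
            xray2=f["xray2"][...],
            case_id=case_id or os.path.splitext(os.path.basename(path))[0],
        )


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple
    test_ids: tuple

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids must be disjoint")


def split_cases(ids, train_frac: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Seeded uniform shuffle; first round(train_frac * n) cases train.

    Rounding is half-up, so 440 cases at 0.8 give 352 train / 88 test.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two cases to split")
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(train_frac * n + 0.5))
    shuffled = [ids[i] for i in order]
    return DatasetSplit(tuple(shuffled[:n_train]), tuple(shuffled[n_train:]))


def resize_for_augment(img: np.ndarray, size: int = AUGMENT_RESIZE) -> np.ndarray:
    """The augmentation's intermediate upsizing stage (150 x 150 default)."""
    return resize(np.asarray(img, dtype=np.float64), (size, size), order=1,
                  anti_aliasing=False)


def norm_stats(samples) -> tuple[float, float]:
    """Dataset-level mean and standard deviation of the training X-rays."""
    pix = np.concatenate(
        [np.stack([s.xray1, s.xray2]).ravel() for s in samples]
    )
    return float(pix.mean()), float(pix.std())


def augment(
    sample: PairedSample,
    seed: int = 0,
    mean: float | None = None,
    sd: float | None = None,
    crop_offset: tuple[int, int] | None = None,
) -> PairedSample:
    """Training-time augmentation of one paired sample.

    Each view is resized to 150x150, then a shared random 128x128 crop is
    taken, then (optionally) both views are standardized by the provided
    dataset mean/sd.  The CT passes through unchanged.  Deterministic for
    a fixed ``seed``; ``crop_offset`` forces the crop corner.
    """
    if sample.xray1.shape != (FINE_SIZE, FINE_SIZE):
        raise ValueError(f"augment expects {FINE_SIZE}x{FINE_SIZE} views")
    rng = np.random.default_rng(seed)
    big1 = resize_for_augment(sample.xray1)
    big2 = resize_for_augment(sample.xray2)
    margin = AUGMENT_RESIZE - FINE_SIZE
    if crop_offset is None:
        crop_offset = tuple(rng.integers(0, margin + 1, size=2))
    r, c = crop_offset
    if not (0 <= r <= margin and 0 <= c <= margin):
        raise ValueError("crop offset out of range")
    x1 = big1[r : r + FINE_SIZE, c : c + FINE_SIZE]
    x2 = big2[r : r + FINE_SIZE, c : c + FINE_SIZE]
    if mean is not None and sd is not None:
        x1 = (x1 - mean) / sd
        x2 = (x2 - mean) / sd
    return PairedSample(sample.ct, x1, x2, sample.case_id)
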
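"""Volumetric image-quality metrics and evaluation runners.

Eleven statistics per ground-truth/reconstruction pair, on cubic volumes
normalized to [0, 1]:

* MAE0 / MSE0 — per-slice mean absolute / squared error (normalized scale),
  averaged over axial slices;
* MAE / MSE — whole-volume errors after mapping back to the CT intensity
  scale (multiply by ``max_intensity``, default 2500).  For cubic volumes
  the identities MAE = scale * MAE0 and MSE = scale^2 * MSE0 hold exactly;
* cosine similarity of the flattened volumes;
* PSNR-1/2/3 — per-slice PSNR averaged (in dB) along the axial, coronal
  and sagittal slicing axes; PSNR-avg — their mean; PSNR-3D — a single
  PSNR over the whole volume;
* SSIM — Gaussian-weighted (11x11 window, sigma 1.5) structural similarity
  averaged over axial slices, dynamic range 1.

PSNR is capped at 100 dB where the ideal value would be infinite so
reports stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import drr, xray_prep
from .types import CTVolume

__all__ = [
    "IntensityScale",
    "MetricReport",
    "AngleSweepReport",
    "mae_slicewise",
    "mse_slicewise",
    "mae_volume",
    "mse_volume",
    "cosine_similarity",
    "psnr",
    "psnr_per_plane",
    "psnr_3d",
    "ssim_volume",
    "evaluate_pair",
    "evaluate_pairs",
    "angle_sweep",
    "report_frame",
]

PSNR_CAP_DB = 100.0
_ROW_LABELS = {
    "mae0": "MAE0",
    "mse0": "MSE0",
    "mae": "MAE",
    "mse": "MSE",
    "cosine": "Cosine Similarity",
    "psnr_3d": "PSNR-3D",
    "psnr_1": "PSNR-1",
    "psnr_2": "PSNR-2",
    "psnr_3": "PSNR-3",
    "psnr_avg": "PSNR-avg",
    "ssim": "SSIM",
}


@dataclass(frozen=True)
class IntensityScale:
    """Denormalization factor mapping [0, 1] volumes back to CT scale."""

    max_intensity: float = 2500.0

    def __post_init__(self):
        if self.max_intensity <= 0:
            raise ValueError("max_intensity must be positive")


@dataclass
class MetricReport:
    mae0: float
    mse0: float
    mae: float
    mse: float
    cosine: float
    psnr_3d: float
    psnr_1: float
    psnr_2: float
    psnr_3: float
    psnr_avg: float
    ssim: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class AngleSweepReport:
    angles: tuple
    reports: tuple  # one MetricReport per angle

    def __post_init__(self):
        if len(self.angles) != len(self.reports):
            raise ValueError("one report per angle required")


def _check_pair(gt, pred, unit_range=True):
    gt = np.asarray(gt, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    if unit_range:
        for name, a in (("gt", gt), ("pred", pred)):
            if a.min() < -1e-9 or a.max() > 1 + 1e-9:
                raise ValueError(f"{name} values must lie in [0, 1]")
    return gt, pred


def mae_slicewise(gt, pred, axis: int = 0) -> float:
    """Mean over slices of each slice's mean absolute difference."""
    gt, pred = _check_pair(gt, pred)
    other = tuple(ax for ax in range(gt.ndim) if ax != axis)
    return float(np.abs(gt - pred).mean(axis=other).mean())


def mse_slicewise(gt, pred, axis: int = 0) -> float:
    gt, pred = _check_pair(gt, pred)
    other = tuple(ax for ax in range(gt.ndim) if ax != axis)
    return float(((gt - pred) ** 2).mean(axis=other).mean())


def mae_volume(gt, pred, scale: IntensityScale = IntensityScale()) -> float:
    """Whole-volume MAE on the denormalized intensity scale."""
    gt, pred = _check_pair(gt, pred)
    return float(np.abs(gt * scale.max_intensity - pred * scale.max_intensity).mean())


def mse_volume(gt, pred, scale: IntensityScale = IntensityScale()) -> float:
    gt, pred = _check_pair(gt, pred)
    diff = gt * scale.max_intensity - pred * scale.max_intensity
    return float((diff**2).mean())


def cosine_similarity(gt, pred) -> float:
    gt, pred = _check_pair(gt, pred, unit_range=False)
    a, b = gt.ravel(), pred.ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(a @ b / (na * nb))


def psnr(gt, pred, peak: float = 1.0) -> float:
    """10 log10(peak^2 / MSE), capped at 100 dB when MSE = 0."""
    gt, pred = _check_pair(gt, pred, unit_range=False)
    mse = float(((gt - pred) ** 2).mean())
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(peak**2 / mse), PSNR_CAP_DB))


def psnr_per_plane(gt, pred, axis: int, peak: float = 1.0) -> float:
    """Mean (in dB) of per-slice PSNR along the given axis."""
    gt, pred = _check_pair(gt, pred, unit_range=False)
    gt = np.moveaxis(gt, axis, 0)
    pred = np.moveaxis(pred, axis, 0)
    return float(np.mean([psnr(g, p, peak) for g, p in zip(gt, pred)]))


def psnr_3d(gt, pred, peak: float = 1.0) -> float:
    """PSNR over the entire volume in one computation."""
    return psnr(gt, pred, peak)


def _gaussian_window(width: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = (width - 1) / 2
    x = np.arange(width) - r
    g = np.exp(-(x**2) / (2 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim_2d(
    a: np.ndarray,
    b: np.ndarray,
    width: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 1.0,
) -> float:
    """Gaussian-weighted SSIM over all fully-interior windows of a slice."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if min(a.shape) < width:
        raise ValueError(f"slice smaller than the {width}x{width} SSIM window")
    w = _gaussian_window(width, sigma)
    wa = sliding_window_view(a, (width, width))
    wb = sliding_window_view(b, (width, width))
    mu_a = np.einsum("hwij,ij->hw", wa, w)
    mu_b = np.einsum("hwij,ij->hw", wb, w)
    e_aa = np.einsum("hwij,ij->hw", wa * wa, w)
    e_bb = np.einsum("hwij,ij->hw", wb * wb, w)
    e_ab = np.einsum("hwij,ij->hw", wa * wb, w)
    var_a = e_aa - mu_a**2
    var_b = e_bb - mu_b**2
    cov = e_ab - mu_a * mu_b
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float((num / den).mean())


def ssim_volume(gt, pred, axis: int = 0, **kwargs) -> float:
    """Mean over axial slices of 2D Gaussian-weighted SSIM."""
    gt, pred = _check_pair(gt, pred)
    gt = np.moveaxis(gt, axis, 0)
    pred = np.moveaxis(pred, axis, 0)
    return float(np.mean([ssim_2d(g, p, **kwargs) for g, p in zip(gt, pred)]))


def evaluate_pair(gt, pred, scale: IntensityScale = IntensityScale()) -> MetricReport:
    """All eleven statistics for one normalized gt/pred pair."""
    gt, pred = _check_pair(gt, pred)
    p1 = psnr_per_plane(gt, pred, 0)
    p2 = psnr_per_plane(gt, pred, 1)
    p3 = psnr_per_plane(gt, pred, 2)
    return MetricReport(
        mae0=mae_slicewise(gt, pred),
        mse0=mse_slicewise(gt, pred),
        mae=mae_volume(gt, pred, scale),
        mse=mse_volume(gt, pred, scale),
        cosine=cosine_similarity(gt, pred),
        psnr_3d=psnr_3d(gt, pred),
        psnr_1=p1,
        psnr_2=p2,
        psnr_3=p3,
        psnr_avg=(p1 + p2 + p3) / 3.0,
        ssim=ssim_volume(gt, pred),
    )


def evaluate_pairs(pairs, scale: IntensityScale = IntensityScale()) -> MetricReport:
    """Plain mean of the per-pair reports over an evaluation set.

    ``pairs``: iterable of (gt, pred) normalized volumes.
    """
    reports = [evaluate_pair(gt, pred, scale) for gt, pred in pairs]
    if not reports:
        raise ValueError("empty evaluation set")
    mean = {
        f.name: float(np.mean([getattr(r, f.name) for r in reports]))
        for f in fields(MetricReport)
    }
    # keep the exact invariant under averaging
    mean["psnr_avg"] = (mean["psnr_1"] + mean["psnr_2"] + mean["psnr_3"]) / 3.0
    return MetricReport(**mean)


def angle_sweep(
    model,
    cases,
    angles=(90.0, 85.0, 80.0, 75.0),
    tf: drr.OpacityTransferFunction | None = None,
    geom: drr.ProjectionGeometry | None = None,
    scale: IntensityScale = IntensityScale(),
    out_size: int | None = None,
) -> AngleSweepReport:
    """Sensitivity of reconstruction quality to the biplanar angle.

    For each angle the lateral radiograph of every case is regenerated at
    that angle (anterior fixed at 0°), preprocessed, fed to ``model`` —
    a callable (xray1, xray2, angle_deg) -> normalized volume, or with a
    2-argument signature — and the reconstruction is scored against the
    normalized ground truth.
    """
    tf = tf or drr.default_xray_tf()
    geom = geom or drr.ProjectionGeometry()
    cases = list(cases)
    if not cases:
        raise ValueError("empty case set")
    reports = []
    for angle in angles:
        pairs = []
        for vol in cases:
            if not isinstance(vol, CTVolume):
                raise TypeError("angle_sweep expects CTVolume cases")
            ant, lat = drr.make_biplanar(vol, tf, lateral_angle_deg=angle, geom=geom)
            size = out_size or vol.shape[0]
            x1 = xray_prep.preprocess_xray(ant.pixels, out_size=size).pixels
            x2 = xray_prep.preprocess_xray(lat.pixels, out_size=size).pixels
            try:
                pred = model(x1, x2, angle)
            except TypeError:
                pred = model(x1, x2)
            gt = np.clip(np.asarray(vol.data, dtype=np.float64) / scale.max_intensity, 0, 1)
            pairs.append((gt, np.asarray(pred, dtype=np.float64)))
        reports.append(evaluate_pairs(pairs, scale))
    return AngleSweepReport(tuple(angles), tuple(reports))


def report_frame(report: MetricReport | AngleSweepReport) -> pd.DataFrame:
    """Tabular view with the conventional row labels; one column per
    condition for an angle sweep."""
    if isinstance(report, MetricReport):
        d = report.as_dict()
        return pd.DataFrame(
            {"Value": [d[k] for k in _ROW_LABELS]},
            index=[_ROW_LABELS[k] for k in _ROW_LABELS],
        )
    data = {
        f"{int(a)} Degree": [r.as_dict()[k] for k in _ROW_LABELS]
        for a, r in zip(report.angles, report.reports)
    }
    return pd.DataFrame(data, index=[_ROW_LABELS[k] for k in _ROW_LABELS])
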
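"""Brute-force loop oracles for the volumetric metrics.

Deliberately naive (explicit Python loops, no vectorisation, no shared
code with the package) so they are an independent route to the same
quantities.
"""

import math

import numpy as np


def mae_slicewise_oracle(gt, pred, axis=0):
    gt = np.moveaxis(np.asarray(gt, float), axis, 0)
    pred = np.moveaxis(np.asarray(pred, float), axis, 0)
    per_slice = []
    for g, p in zip(gt, pred):
        total, count = 0.0, 0
        for gv, pv in zip(g.ravel(), p.ravel()):
            total += abs(gv - pv)
            count += 1
        per_slice.append(total / count)
    return sum(per_slice) / len(per_slice)


def mse_slicewise_oracle(gt, pred, axis=0):
    gt = np.moveaxis(np.asarray(gt, float), axis, 0)
    pred = np.moveaxis(np.asarray(pred, float), axis, 0)
    per_slice = []
    for g, p in zip(gt, pred):
        total, count = 0.0, 0
        for gv, pv in zip(g.ravel(), p.ravel()):
            total += (gv - pv) ** 2
            count += 1
        per_slice.append(total / count)
    return sum(per_slice) / len(per_slice)


def mae_volume_oracle(gt, pred, scale):
    total, count = 0.0, 0
    for gv, pv in zip(np.asarray(gt, float).ravel(), np.asarray(pred, float).ravel()):
        total += abs(gv * scale - pv * scale)
        count += 1
    return total / count


def mse_volume_oracle(gt, pred, scale):
    total, count = 0.0, 0
    for gv, pv in zip(np.asarray(gt, float).ravel(), np.asarray(pred, float).ravel()):
        total += (gv * scale - pv * scale) ** 2
        count += 1
    return total / count


def cosine_oracle(gt, pred):
    dot = na = nb = 0.0
    for gv, pv in zip(np.asarray(gt, float).ravel(), np.asarray(pred, float).ravel()):
        dot += gv * pv
        na += gv * gv
        nb += pv * pv
    return dot / (math.sqrt(na) * math.sqrt(nb))


def psnr_oracle(gt, pred, peak=1.0, cap=100.0):
    total, count = 0.0, 0
    for gv, pv in zip(np.asarray(gt, float).ravel(), np.asarray(pred, float).ravel()):
        total += (gv - pv) ** 2
        count += 1
    mse = total / count
    if mse == 0.0:
        return cap
    return min(10.0 * math.log10(peak**2 / mse), cap)


def psnr_per_plane_oracle(gt, pred, axis):
    gt = np.moveaxis(np.asarray(gt, float), axis, 0)
    pred = np.moveaxis(np.asarray(pred, float), axis, 0)
    vals = [psnr_oracle(g, p) for g, p in zip(gt, pred)]
    return sum(vals) / len(vals)


def _gauss_window(width=11, sigma=1.5):
    r = (width - 1) / 2
    w = np.empty((width, width))
    for i in range(width):
        for j in range(width):
            w[i, j] = math.exp(-((i - r) ** 2 + (j - r) ** 2) / (2 * sigma**2))
    return w / w.sum()


def ssim_2d_oracle(a, b, width=11, sigma=1.5, k1=0.01, k2=0.03, dr=1.0):
    """Per-window double loop over all fully-interior positions."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    w = _gauss_window(width, sigma)
    c1, c2 = (k1 * dr) ** 2, (k2 * dr) ** 2
    vals = []
    for i in range(a.shape[0] - width + 1):
        for j in range(a.shape[1] - width + 1):
            wa = a[i : i + width, j : j + width]
            wb = b[i : i + width, j : j + width]
            mu_a = float((w * wa).sum())
            mu_b = float((w * wb).sum())
            var_a = float((w * wa * wa).sum()) - mu_a**2
            var_b = float((w * wb * wb).sum()) - mu_b**2
            cov = float((w * wa * wb).sum()) - mu_a * mu_b
            vals.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
            )
    return sum(vals) / len(vals)


def ssim_volume_oracle(gt, pred, **kw):
    gt = np.asarray(gt, float)
    pred = np.asarray(pred, float)
    vals = [ssim_2d_oracle(g, p, **kw) for g, p in zip(gt, pred)]
    return sum(vals) / len(vals)
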
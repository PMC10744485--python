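"""Scikit-learn style estimators over the reconstruction core.

:class:`BiplanarCTReconstructor` wraps the two-view fusion GAN as a
fit/predict estimator so it composes with sklearn pipelines and model
selection; :class:`XRayPreprocessor` exposes the radiograph preprocessing
chain as a transformer.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import eval_metrics, recon_gan, xray_prep
from .recon_gan import GanConfig, LossWeights
from .types import PairedSample

__all__ = ["BiplanarCTReconstructor", "XRayPreprocessor"]


class BiplanarCTReconstructor(BaseEstimator):
    """GAN-based reconstruction of a 3D volume from two radiographs.

    Parameters mirror the training configuration: Adam learning rate and
    betas, epoch count, network width and output edge length, and the
    relative weights of the generator's objective terms.

    After :meth:`fit`, the trained networks are available as
    ``generator_`` / ``discriminator_`` and the per-epoch loss means as
    ``history_``.
    """

    def __init__(
        self,
        learning_rate: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.99,
        n_epochs: int = 10,
        base_channels: int = 16,
        volume_size: int = 128,
        w_gan: float = 0.1,
        w_recon: float = 10.0,
        w_proj: float = 10.0,
        w_fm: float = 1.0,
        w_idt: float = 1.0,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.n_epochs = n_epochs
        self.base_channels = base_channels
        self.volume_size = volume_size
        self.w_gan = w_gan
        self.w_recon = w_recon
        self.w_proj = w_proj
        self.w_fm = w_fm
        self.w_idt = w_idt
        self.seed = seed

    def _config(self) -> GanConfig:
        return GanConfig(
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            n_epochs=self.n_epochs,
            base_channels=self.base_channels,
            volume_size=self.volume_size,
            loss_weights=LossWeights(
                self.w_gan, self.w_recon, self.w_proj, self.w_fm, self.w_idt
            ),
            seed=self.seed,
        )

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        s = self.volume_size
        if X.ndim != 4 or X.shape[1] != 2 or X.shape[2:] != (s, s):
            raise ValueError(
                f"X must have shape (n_samples, 2, {s}, {s}); got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        return X

    def fit(self, X, y, log_dir: str | None = None):
        """Train on paired views ``X`` (n, 2, S, S) and volumes ``y``
        (n, S, S, S) with values in [0, 1]."""
        X = self._validate_X(X)
        y = np.asarray(y, dtype=np.float64)
        s = self.volume_size
        if y.shape != (len(X), s, s, s):
            raise ValueError(f"y must have shape (n_samples, {s}, {s}, {s})")
        dataset = [
            PairedSample(ct=vol, xray1=views[0], xray2=views[1], case_id=str(i))
            for i, (views, vol) in enumerate(zip(X, y))
        ]
        result = recon_gan.train(dataset, self._config(), log_dir=log_dir)
        self.generator_ = result.generator
        self.discriminator_ = result.discriminator
        self.history_ = result.history
        self.n_features_in_ = X[0].size
        return self

    def predict(self, X) -> np.ndarray:
        """Reconstruct one volume per sample; output in [0, 1]."""
        check_is_fitted(self, "generator_")
        X = self._validate_X(X)
        return np.stack(
            [self.generator_.predict_volume(v[0], v[1]) for v in X]
        )

    def score(self, X, y) -> float:
        """Mean PSNR-3D (dB) of the reconstructions against ``y``."""
        pred = self.predict(X)
        y = np.asarray(y, dtype=np.float64)
        return float(
            np.mean([eval_metrics.psnr_3d(g, p) for g, p in zip(y, pred)])
        )


class XRayPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer applying the radiograph preprocessing chain."""

    def __init__(self, out_size: int = 128, threshold="otsu"):
        self.out_size = out_size
        self.threshold = threshold

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X[0]).size
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack(
            [
                xray_prep.preprocess_xray(
                    img, out_size=self.out_size, threshold=self.threshold
                ).pixels
                for img in X
            ]
        )
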
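"""scikit-learn style front end for the motion simulator.

:class:`RespiratoryMotionSimulator` wraps phantom loading, the training loop
and prediction behind the familiar ``fit`` / ``predict`` /
``get_params`` / ``set_params`` surface, so the simulator composes with
sklearn model-selection utilities. The module-level :func:`rms.train.train`
and :func:`rms.evaluate.evaluate_model` functions remain thin wrappers
around the same machinery.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .phantom import PhantomCase, iter_split
from .train import TrainConfig, fit_cases

__all__ = ["RespiratoryMotionSimulator"]


class RespiratoryMotionSimulator(BaseEstimator):
    """Predicts a 9-phase breathing cycle from one end-of-inhale image.

    Parameters mirror :class:`rms.train.TrainConfig`. ``fit`` accepts either
    a phantom dataset directory or a list of :class:`rms.phantom.PhantomCase`
    objects; ``predict`` maps a 2D EOI image (at the training resolution) to
    ``(dvfs (9, 2, H, W), phase images (9, H, W))``.

    Attributes set by ``fit`` (sklearn convention, trailing underscore):
    ``net_`` (the trained network), ``checkpoint_`` and ``history_``.
    """

    def __init__(self, epochs: int = 90, batch_size: int = 4,
                 learning_rate: float = 1e-3, seed: int = 0,
                 smooth_weight: float = 0.05, mse_weight: float = 30.0,
                 ncc_weight: float = 1.0, ncc_window: int = 9,
                 image_size: int = 32, base_channels: int = 8,
                 latent_dim: int = 512, lstm_layers: int = 2,
                 max_disp: float | None = None, val_interval: int = 5):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.smooth_weight = smooth_weight
        self.mse_weight = mse_weight
        self.ncc_weight = ncc_weight
        self.ncc_window = ncc_window
        self.image_size = image_size
        self.base_channels = base_channels
        self.latent_dim = latent_dim
        self.lstm_layers = lstm_layers
        self.max_disp = max_disp
        self.val_interval = val_interval

    def _config(self) -> TrainConfig:
        return TrainConfig(**self.get_params())

    def fit(self, X, y=None):
        """Train on a dataset directory or a list of phantom cases."""
        if isinstance(X, (str, Path)):
            train_cases = list(iter_split(X, "train"))
            val_cases = list(iter_split(X, "test"))
        else:
            train_cases = list(X)
            val_cases = []
        ck = fit_cases(train_cases, val_cases, self._config())
        self.checkpoint_ = ck
        self.net_ = ck.build_net()
        self.history_ = ck.history
        return self

    def predict(self, X):
        """EOI image(s) -> (dvfs, phase images); accepts (H, W) or (N, H, W)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            return self.net_.forward(X)
        out = [self.net_.forward(x) for x in X]
        return np.stack([o[0] for o in out]), np.stack([o[1] for o in out])

    def score(self, X, y=None) -> float:
        """Mean Dice over the test split of a dataset directory, or over the
        given phantom cases."""
        self._check_fitted()
        from .evaluate import evaluate_cases, model_predictor

        if isinstance(X, (str, Path)):
            cases = list(iter_split(X, "test"))
        else:
            cases = list(X)
        rep = evaluate_cases(model_predictor(self.net_), cases)
        return rep.summary["dice_mean"]

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise AttributeError("this RespiratoryMotionSimulator is not fitted yet")
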
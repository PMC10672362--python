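"""Scikit-learn style estimators for few-shot despeckling.

Each estimator wraps one training recipe behind the familiar
``fit(noisy, clean)`` / ``transform(image)`` contract, composes with
sklearn's ``get_params`` / ``set_params`` / ``clone``, and exposes its
fitted state through trailing-underscore attributes (``model_``,
``loss_trace_``, ``n_parameters_``).  ``fit`` consumes a *single* image
pair — that is the point of the method — and ``transform`` despeckles any
number of images from the same (or, after resampling adaptation, another)
acquisition system.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .networks import count_parameters
from .patching import AnalysisPatchConfig
from .speckle_sim import LogImage
from .system_model import OCTSystemSpec
from .training import TrainConfig, despeckle_image, few_shot_fit

__all__ = [
    "RNNDespeckler",
    "DRNNDespeckler",
    "RNNGANDespeckler",
    "UNetDespeckler",
]


def _as_log_image(X) -> LogImage:
    if isinstance(X, LogImage):
        return X
    return LogImage(values=np.asarray(X, dtype=float))


class _BaseDespeckler(BaseEstimator):
    """Shared plumbing; subclasses define ``_method`` and extra params."""

    _method = ""

    def __init__(
        self,
        lr=1e-4,
        beta1=0.5,
        beta2=0.9,
        epochs=8,
        batch_size=256,
        early_stop_patience=2,
        early_stop_tol=0.01,
        region=None,
        random_state=0,
        source_spec=None,
    ):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.epochs = epochs
        self.batch_size = batch_size
        self.early_stop_patience = early_stop_patience
        self.early_stop_tol = early_stop_tol
        self.region = region
        self.random_state = random_state
        self.source_spec = source_spec

    # -- subclass hooks -----------------------------------------------------

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr=self.lr,
            beta1=self.beta1,
            beta2=self.beta2,
            epochs_content=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
            early_stop_patience=self.early_stop_patience,
            early_stop_tol=self.early_stop_tol,
        )

    def _fit_kwargs(self) -> dict:
        return {}

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        """Train on one noisy tomogram ``X`` and its clean counterpart ``y``."""
        noisy = _as_log_image(X)
        clean = _as_log_image(y)
        self.model_ = few_shot_fit(
            noisy,
            clean,
            method=self._method,
            region=self.region,
            cfg=self._train_config(),
            source_spec=self.source_spec,
            **self._fit_kwargs(),
        )
        self.loss_trace_ = list(self.model_.loss_trace)
        self.n_parameters_ = count_parameters(self.model_)
        return self

    def transform(self, X):
        """Despeckle a tomogram; returns the input's type (array or image)."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        out = despeckle_image(_as_log_image(X), self.model_)
        return out if isinstance(X, LogImage) else out.values

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    # alias: despeckling reads naturally as prediction too
    def predict(self, X):
        return self.transform(X)


class RNNDespeckler(_BaseDespeckler):
    """Patch-to-pixel recurrent despeckler.

    A recurrent cell of width ``hidden`` walks the ``patch_size[0]`` depth
    steps of each analysis patch and a linear head emits the anchor pixel.
    """

    _method = "rnn"

    def __init__(
        self,
        hidden=1000,
        patch_size=(15, 15),
        lr=1e-4,
        beta1=0.5,
        beta2=0.9,
        epochs=8,
        batch_size=256,
        early_stop_patience=2,
        early_stop_tol=0.01,
        region=None,
        random_state=0,
        source_spec=None,
    ):
        super().__init__(
            lr=lr,
            beta1=beta1,
            beta2=beta2,
            epochs=epochs,
            batch_size=batch_size,
            early_stop_patience=early_stop_patience,
            early_stop_tol=early_stop_tol,
            region=region,
            random_state=random_state,
            source_spec=source_spec,
        )
        self.hidden = hidden
        self.patch_size = patch_size

    def _fit_kwargs(self):
        lt, nx = self.patch_size
        return {
            "hidden": self.hidden,
            "patch_cfg": AnalysisPatchConfig(Lt=lt, Nx=nx, P=1),
        }


class DRNNDespeckler(RNNDespeckler):
    """Deblurring variant: identical architecture, low-passed input.

    The training and test tomograms are blurred with a normalized
    ``deblur_size`` x ``deblur_size`` Gaussian (std ``deblur_sigma``)
    before patch extraction, recasting despeckling as deblurring.
    """

    _method = "drnn"

    def __init__(
        self,
        hidden=1000,
        patch_size=(15, 15),
        deblur_size=7,
        deblur_sigma=1.0,
        lr=1e-4,
        beta1=0.5,
        beta2=0.9,
        epochs=8,
        batch_size=256,
        early_stop_patience=2,
        early_stop_tol=0.01,
        region=None,
        random_state=0,
        source_spec=None,
    ):
        super().__init__(
            hidden=hidden,
            patch_size=patch_size,
            lr=lr,
            beta1=beta1,
            beta2=beta2,
            epochs=epochs,
            batch_size=batch_size,
            early_stop_patience=early_stop_patience,
            early_stop_tol=early_stop_tol,
            region=region,
            random_state=random_state,
            source_spec=source_spec,
        )
        self.deblur_size = deblur_size
        self.deblur_sigma = deblur_sigma

    def _fit_kwargs(self):
        kwargs = super()._fit_kwargs()
        kwargs["deblur"] = (self.deblur_size, self.deblur_sigma)
        return kwargs


class RNNGANDespeckler(_BaseDespeckler):
    """Patch-to-patch recurrent generator with adversarial refinement.

    Content (MSE) stage first, then a second stage against a two-FC-layer
    patch discriminator with generator loss ``MSE + lambda_adv * ADV``;
    overlapping patch predictions are averaged at inference.
    """

    _method = "rnn_gan"

    def __init__(
        self,
        hidden=1000,
        patch_size=(15, 15),
        epochs_adv=20,
        lambda_adv=1e-3,
        disc_hidden=128,
        stride=(1, 1),
        lr=1e-4,
        beta1=0.5,
        beta2=0.9,
        epochs=8,
        batch_size=256,
        early_stop_patience=2,
        early_stop_tol=0.01,
        region=None,
        random_state=0,
        source_spec=None,
    ):
        super().__init__(
            lr=lr,
            beta1=beta1,
            beta2=beta2,
            epochs=epochs,
            batch_size=batch_size,
            early_stop_patience=early_stop_patience,
            early_stop_tol=early_stop_tol,
            region=region,
            random_state=random_state,
            source_spec=source_spec,
        )
        self.hidden = hidden
        self.patch_size = patch_size
        self.epochs_adv = epochs_adv
        self.lambda_adv = lambda_adv
        self.disc_hidden = disc_hidden
        self.stride = stride

    def _train_config(self):
        cfg = super()._train_config()
        cfg.epochs_adv = self.epochs_adv
        cfg.lambda_adv = self.lambda_adv
        cfg.disc_hidden = self.disc_hidden
        return cfg

    def _fit_kwargs(self):
        lt, nx = self.patch_size
        return {
            "hidden": self.hidden,
            "patch_cfg": AnalysisPatchConfig(Lt=lt, Nx=nx, P=nx),
            "stride": self.stride,
        }


class UNetDespeckler(_BaseDespeckler):
    """One-shot U-Net trained on random crops of the single pair.

    The default (depth 4, base 32) has about 7.8 million parameters;
    smaller configurations train in seconds on a CPU.
    """

    _method = "unet"

    def __init__(
        self,
        depth=4,
        base_channels=32,
        crop=64,
        crops_per_epoch=128,
        lr=1e-4,
        beta1=0.5,
        beta2=0.9,
        epochs=8,
        batch_size=256,
        early_stop_patience=2,
        early_stop_tol=0.01,
        region=None,
        random_state=0,
        source_spec=None,
    ):
        super().__init__(
            lr=lr,
            beta1=beta1,
            beta2=beta2,
            epochs=epochs,
            batch_size=batch_size,
            early_stop_patience=early_stop_patience,
            early_stop_tol=early_stop_tol,
            region=region,
            random_state=random_state,
            source_spec=source_spec,
        )
        self.depth = depth
        self.base_channels = base_channels
        self.crop = crop
        self.crops_per_epoch = crops_per_epoch

    def _train_config(self):
        cfg = super()._train_config()
        cfg.unet_crop = self.crop
        cfg.unet_crops_per_epoch = self.crops_per_epoch
        return cfg

    def _fit_kwargs(self):
        return {"unet_depth": self.depth, "unet_base_channels": self.base_channels}
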
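"""Few-shot fitting and full-image inference.

Training consumes a *single* noisy/clean tomogram pair (or a region of
one).  The content stage minimizes the mean squared error between patch
predictions and clean targets with Adam; the optional adversarial stage
adds a small non-saturating GAN term, with the clean patches as the "real"
distribution and the generator's outputs as "fake":

    L_G = L_MSE + lambda * L_ADV .

Early stopping guards against over-fitting the one training image, which
shows up as blurry outputs.  Everything is deterministic given the config
seed: identical seeds yield bit-identical parameters and loss traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np

from ._nn import Adam
from .networks import (
    DespecklerModel,
    DiscriminatorParams,
    RNNParams,
    UNetParams,
    deblur_preprocess,
    discriminator_backward,
    init_discriminator_params,
    init_rnn_params,
    init_unet_params,
    rnn_backward,
    rnn_forward,
    unet_backward,
    unet_forward,
)
from .patching import (
    AnalysisPatchConfig,
    Normalization,
    PatchDataset,
    build_dataset,
    iter_patches,
    overlap_average_reconstruct,
)
from .speckle_sim import LogImage
from .system_model import InvalidParameterError, OCTSystemSpec

__all__ = [
    "TrainConfig",
    "train_content",
    "train_adversarial",
    "despeckle_image",
    "few_shot_fit",
]


@dataclass
class TrainConfig:
    """Optimization settings for both training stages.

    Defaults follow the despeckling recipe: Adam with ``beta1=0.5``,
    ``beta2=0.9`` and initial learning rate 1e-4; 8 content epochs (the
    useful range is 5–12) and 20 adversarial epochs (range 10–30);
    ``lambda_adv`` balances the adversarial term against the MSE.
    """

    lr: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.9
    epochs_content: int = 8
    epochs_adv: int = 20
    lambda_adv: float = 1e-3
    batch_size: int = 256
    seed: int = 0
    early_stop_patience: int = 2
    early_stop_tol: float = 0.01
    disc_hidden: int = 128
    unet_crop: int = 64
    unet_crops_per_epoch: int = 128

    def __post_init__(self) -> None:
        if not self.lr > 0:
            raise InvalidParameterError("lr must be > 0")
        if self.epochs_content < 1 or self.epochs_adv < 1:
            raise InvalidParameterError("epochs must be >= 1")
        if self.lambda_adv < 0:
            raise InvalidParameterError("lambda_adv must be >= 0")


# ---------------------------------------------------------------------------
# content stage
# ---------------------------------------------------------------------------


def _check_finite(loss: float, context: str) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(
            f"training diverged ({context}: loss={loss}); "
            "lower the learning rate or shrink the batch"
        )


def _early_stop(trace: list, tol: float, patience: int) -> bool:
    if len(trace) < patience + 1:
        return False
    recent = trace[-(patience + 1) :]
    return all(
        (recent[i] - recent[i + 1]) / max(recent[i], 1e-12) < tol
        for i in range(patience)
    )


def _rnn_targets(batch_targets: np.ndarray, P: int) -> np.ndarray:
    if P == 1:
        return batch_targets[..., None]  # (B, Lt) -> (B, Lt, 1)
    return batch_targets


def train_content(model: DespecklerModel, data, cfg: TrainConfig):
    """MSE stage: fit the model's parameters to the one-shot dataset.

    For the RNN-family methods ``data`` is a :class:`PatchDataset` (for the
    deblurring variant its inputs must come from the low-passed image); for
    the U-Net it is the normalized ``(noisy01, clean01)`` array pair from
    which random crops are drawn each epoch.  Returns ``(model, trace)``
    with the per-epoch mean training loss; stops early once the loss
    plateaus.
    """
    if model.method == "unet":
        return _train_unet_content(model, data, cfg)
    if len(data) == 0:
        raise InvalidParameterError("empty dataset")
    params: RNNParams = model.params
    store = params.as_dict()
    opt = Adam(store, lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(cfg.seed)
    trace = []
    inputs = data.inputs
    targets = _rnn_targets(data.targets, params.P)
    m = inputs.shape[0]
    for _epoch in range(cfg.epochs_content):
        order = rng.permutation(m)
        epoch_loss = 0.0
        for start in range(0, m, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            out, cache = rnn_forward(inputs[sel], params, cache=True)
            resid = out - targets[sel]
            with np.errstate(over="ignore", invalid="ignore"):
                loss = float(np.mean(resid**2))
            _check_finite(loss, "content stage")
            epoch_loss += loss * sel.size
            grads = rnn_backward((2.0 / resid.size) * resid, cache, params)
            opt.step(grads)
        trace.append(epoch_loss / m)
        if _early_stop(trace, cfg.early_stop_tol, cfg.early_stop_patience):
            break
    model.loss_trace.extend(trace)
    return model, trace


def _draw_crops(
    rng: np.random.Generator,
    noisy01: np.ndarray,
    clean01: np.ndarray,
    crop: int,
    count: int,
):
    rows = rng.integers(0, noisy01.shape[0] - crop + 1, size=count)
    cols = rng.integers(0, noisy01.shape[1] - crop + 1, size=count)
    xs = np.stack([noisy01[r : r + crop, c : c + crop] for r, c in zip(rows, cols)])
    ys = np.stack([clean01[r : r + crop, c : c + crop] for r, c in zip(rows, cols)])
    return xs.astype(np.float32), ys.astype(np.float32)


def _train_unet_content(model: DespecklerModel, data, cfg: TrainConfig):
    noisy01, clean01 = data
    params: UNetParams = model.params
    crop = min(cfg.unet_crop, *(s // 2**params.depth * 2**params.depth for s in noisy01.shape))
    if crop < 2**params.depth:
        raise InvalidParameterError("training image too small for one U-Net crop")
    opt = Adam(params.weights, lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(cfg.seed)
    trace = []
    batch = max(1, min(16, cfg.unet_crops_per_epoch))
    for _epoch in range(cfg.epochs_content):
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, cfg.unet_crops_per_epoch, batch):
            count = min(batch, cfg.unet_crops_per_epoch - start)
            xs, ys = _draw_crops(rng, noisy01, clean01, crop, count)
            model.n_crops_drawn += count
            out, cache = unet_forward(xs, params, cache=True)
            resid = out - ys
            loss = float(np.mean(resid**2))
            _check_finite(loss, "unet content stage")
            epoch_loss += loss * count
            n_seen += count
            grads = unet_backward((2.0 / resid.size) * resid, cache, params)
            opt.step(grads)
        trace.append(epoch_loss / n_seen)
        if _early_stop(trace, cfg.early_stop_tol, cfg.early_stop_patience):
            break
    model.loss_trace.extend(trace)
    return model, trace


# ---------------------------------------------------------------------------
# adversarial stage
# ---------------------------------------------------------------------------


def train_adversarial(
    generator: DespecklerModel,
    discriminator: DiscriminatorParams,
    data: PatchDataset,
    cfg: TrainConfig,
    n_steps: Optional[int] = None,
):
    """Alternate discriminator / generator updates on clean-vs-predicted patches.

    The generator must already be content-trained (its weights initialize
    this stage).  Per batch the discriminator sees clean target patches as
    real and generator outputs as fake; the generator then descends
    ``MSE + lambda_adv * BCE(D(prediction), real)`` (non-saturating form;
    with ``lambda_adv=0`` the update is exactly a content step).  Returns
    ``(generator, discriminator, history)`` where history logs per-epoch
    generator/discriminator losses and discriminator accuracy.
    """
    params: RNNParams = generator.params
    if params.P != params.n_inputs:
        raise InvalidParameterError("adversarial stage needs a patch head (P=Nx)")
    optG = Adam(params.as_dict(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    optD = Adam(discriminator.as_dict(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(cfg.seed + 1)
    m = len(data)
    inputs = data.inputs
    targets = data.targets
    history = {"g_loss": [], "d_loss": [], "d_accuracy": []}
    saturated = 0
    steps_done = 0
    for _epoch in range(cfg.epochs_adv):
        order = rng.permutation(m)
        g_loss = d_loss = acc = 0.0
        n_batches = 0
        for start in range(0, m, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            pred, cache = rnn_forward(inputs[sel], params, cache=True)

            # --- discriminator step (fake detached) -----------------------
            real_flat = targets[sel].reshape(sel.size, -1)
            fake_flat = pred.reshape(sel.size, -1)
            loss_r, grads_r, _ = discriminator_backward(
                real_flat, np.ones((sel.size, 1), dtype=np.float32), discriminator
            )
            loss_f, grads_f, _ = discriminator_backward(
                fake_flat, np.zeros((sel.size, 1), dtype=np.float32), discriminator
            )
            optD.step({k: grads_r[k] + grads_f[k] for k in grads_r})
            batch_d = loss_r + loss_f
            d_loss += batch_d
            if batch_d < 1e-3:
                saturated += 1
                if saturated == 20:
                    warnings.warn(
                        "discriminator saturated (near-zero loss for 20 "
                        "batches); consider rebalancing learning rates",
                        stacklevel=2,
                    )
            else:
                saturated = 0

            # --- accuracy bookkeeping ------------------------------------
            from .networks import discriminator_forward

            acc += 0.5 * (
                float(np.mean(discriminator_forward(targets[sel], discriminator) > 0.5))
                + float(np.mean(discriminator_forward(pred, discriminator) <= 0.5))
            )

            # --- generator step -------------------------------------------
            resid = pred - targets[sel]
            mse = float(np.mean(resid**2))
            _check_finite(mse, "adversarial stage")
            dout = (2.0 / resid.size) * resid
            if cfg.lambda_adv > 0:
                adv_loss, _, dflat = discriminator_backward(
                    fake_flat, np.ones((sel.size, 1), dtype=np.float32), discriminator
                )
                dout = dout + cfg.lambda_adv * dflat.reshape(pred.shape)
                g_loss += mse + cfg.lambda_adv * adv_loss
            else:
                g_loss += mse
            optG.step(rnn_backward(dout.astype(pred.dtype), cache, params))
            n_batches += 1
            steps_done += 1
            if n_steps is not None and steps_done >= n_steps:
                break
        history["g_loss"].append(g_loss / n_batches)
        history["d_loss"].append(d_loss / n_batches)
        history["d_accuracy"].append(acc / n_batches)
        if n_steps is not None and steps_done >= n_steps:
            break
    generator.loss_trace.extend(history["g_loss"])
    return generator, discriminator, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _rnn_batched(patches: np.ndarray, params: RNNParams, chunk: int = 8192):
    outs = []
    for start in range(0, patches.shape[0], chunk):
        outs.append(rnn_forward(patches[start : start + chunk], params))
    return np.concatenate(outs, axis=0)


def despeckle_image(image: LogImage, model: DespecklerModel) -> LogImage:
    """Full-size despeckled prediction of a tomogram.

    The image is normalized to [0,1] by its own min-max (robust to
    brightness offsets across systems), the deblurring variant low-passes
    it first, patch-to-pixel methods fill every pixel from its anchored
    analysis patch, the patch-to-patch method averages overlapping patch
    predictions, and the U-Net runs on the reflect-padded full frame.  The
    output is mapped back to dB with the same affine.
    """
    cfg = model.patch_cfg
    if cfg is not None and (image.shape[0] < cfg.Lt or image.shape[1] < cfg.Nx):
        raise InvalidParameterError("image smaller than the analysis patch")
    work = image
    if model.method == "drnn":
        size, sigma = model.deblur_filter
        work = deblur_preprocess(work, size=size, sigma=sigma)
    norm = Normalization.from_image(work)
    img01 = LogImage(values=norm.apply(work.values), pitches=work.pitches)

    if model.method in ("rnn", "drnn"):
        patches, _anchors = iter_patches(img01, cfg, stride=(1, 1))
        outputs = _rnn_batched(patches.astype(np.float32), model.params)
        values01 = outputs[:, -1, 0].reshape(image.shape)
    elif model.method == "rnn_gan":
        patches, anchors = iter_patches(img01, cfg, stride=model.stride)
        preds = _rnn_batched(patches.astype(np.float32), model.params)
        values01 = overlap_average_reconstruct(preds, anchors, image.shape, cfg)
    elif model.method == "unet":
        stride = 2**model.params.depth
        pad_r = (-image.shape[0]) % stride
        pad_c = (-image.shape[1]) % stride
        padded = np.pad(img01.values, ((0, pad_r), (0, pad_c)), mode="reflect")
        out = unet_forward(padded[None].astype(np.float32), model.params)[0]
        values01 = out[: image.shape[0], : image.shape[1]]
    else:  # pragma: no cover
        raise InvalidParameterError(f"unknown method {model.method!r}")
    return LogImage(
        values=norm.invert(np.asarray(values01, dtype=float)),
        pitches=image.pitches,
        dynamic_range=image.dynamic_range,
    )


# ---------------------------------------------------------------------------
# one-call fitting
# ---------------------------------------------------------------------------


def few_shot_fit(
    noisy: LogImage,
    clean: LogImage,
    method: str = "rnn",
    region=None,
    cfg: Optional[TrainConfig] = None,
    patch_cfg: Optional[AnalysisPatchConfig] = None,
    hidden: int = 1000,
    unet_depth: int = 4,
    unet_base_channels: int = 32,
    stride: tuple = (1, 1),
    deblur: tuple = (7, 1.0),
    source_spec: Optional[OCTSystemSpec] = None,
) -> DespecklerModel:
    """Train a despeckler from one paired tomogram (or a region of it).

    Dispatches dataset construction (analysis patches for the RNN family,
    random square crops for the U-Net), runs the content stage and — for
    the adversarial method — the GAN refinement stage, and returns a sealed
    model carrying its patch geometry, normalization and source system.
    """
    cfg = cfg or TrainConfig()
    if method in ("rnn", "drnn"):
        patch_cfg = patch_cfg or AnalysisPatchConfig(P=1)
        if patch_cfg.P != 1:
            raise InvalidParameterError("patch-to-pixel methods require P=1")
    elif method == "rnn_gan":
        patch_cfg = patch_cfg or AnalysisPatchConfig(Nx=15, P=15)
        if patch_cfg.P != patch_cfg.Nx:
            raise InvalidParameterError("rnn_gan requires P=Nx")

    if method == "unet":
        params = init_unet_params(unet_depth, unet_base_channels, seed=cfg.seed)
        norm = Normalization.from_image(noisy)
        rows, cols = _region_arrays(region, noisy.shape)
        noisy01 = norm.apply(noisy.values[rows, cols])
        clean01 = norm.apply(clean.values[rows, cols])
        model = DespecklerModel(
            method="unet",
            params=params,
            patch_cfg=None,
            normalization=norm,
            source_spec=source_spec,
        )
        model, _ = train_content(model, (noisy01, clean01), cfg)
        return model

    train_noisy = noisy
    deblur_filter = None
    if method == "drnn":
        deblur_filter = deblur
        train_noisy = deblur_preprocess(noisy, size=deblur[0], sigma=deblur[1])
    data = build_dataset(train_noisy, clean, patch_cfg, region)
    params = init_rnn_params(patch_cfg.Nx, hidden, patch_cfg.P, seed=cfg.seed)
    model = DespecklerModel(
        method=method,
        params=params,
        patch_cfg=patch_cfg,
        normalization=data.normalization,
        source_spec=source_spec,
        deblur_filter=deblur_filter,
        stride=stride,
    )
    model, _ = train_content(model, data, cfg)
    if method == "rnn_gan":
        disc = init_discriminator_params(
            (patch_cfg.Lt, patch_cfg.Nx), hidden=cfg.disc_hidden, seed=cfg.seed + 2
        )
        model, _disc, _hist = train_adversarial(model, disc, data, cfg)
    return model


def _region_arrays(region, shape):
    if region is None:
        return slice(None), slice(None)
    (r0, r1), (c0, c1) = region
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise InvalidParameterError(f"region {region} outside image {shape}")
    return slice(r0, r1), slice(c0, c1)
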
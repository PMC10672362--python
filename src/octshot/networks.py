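"""Predictor architectures for patch-based despeckling.

Four predictors share one contract — map a normalized noisy analysis patch
(or image crop) to its clean counterpart:

* the RNN encoder–decoder: one recurrent cell walked down the ``Lt`` depth
  steps of an analysis patch, each step seeing the ``Nx`` lateral neighbors
  at that depth, wrapped with a linear fully connected head of output width
  ``P`` (1 = patch-to-pixel, ``Nx`` = patch-to-patch);
* the deblurring variant (DRNN): the identical architecture fed a low-pass
  filtered tomogram, so despeckling is recast as deblurring;
* a two-FC-layer patch discriminator for the adversarial refinement stage;
* a conventional U-Net trained on random crops of the single training pair.

All forward passes are deterministic given parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import convolve as nd_convolve

from . import _nn
from .patching import AnalysisPatchConfig, Normalization
from .speckle_sim import LogImage
from .system_model import InvalidParameterError, OCTSystemSpec

__all__ = [
    "RNNParams",
    "DiscriminatorParams",
    "UNetParams",
    "DespecklerModel",
    "init_rnn_params",
    "init_discriminator_params",
    "init_unet_params",
    "rnn_forward",
    "predict_pixel",
    "predict_patch",
    "gaussian_kernel",
    "deblur_preprocess",
    "discriminator_forward",
    "discriminator_input_gradient",
    "unet_forward",
    "count_parameters",
    "model_manifest",
    "save_model",
    "load_model",
]


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# RNN encoder–decoder
# ---------------------------------------------------------------------------


@dataclass
class RNNParams:
    """Weights of the recurrent cell plus its fully connected head.

    ``z_t = ReLU(y_t W_zy + z_{t-1} W_zz + b)``, ``x_t = z_t W_head + b_head``
    with the zero state at the first step.
    """

    W_zy: np.ndarray  # (Nx, nn)
    W_zz: np.ndarray  # (nn, nn)
    b: np.ndarray  # (nn,)
    head_W: np.ndarray  # (nn, P)
    head_b: np.ndarray  # (P,)

    def __post_init__(self) -> None:
        nx, nn = self.W_zy.shape
        if self.W_zz.shape != (nn, nn) or self.b.shape != (nn,):
            raise InvalidParameterError("recurrent weight shapes inconsistent")
        if self.head_W.shape[0] != nn or self.head_b.shape != (self.head_W.shape[1],):
            raise InvalidParameterError("head shapes inconsistent")
        for arr in self.as_dict().values():
            if not np.all(np.isfinite(arr)):
                raise InvalidParameterError("non-finite RNN parameter")

    @property
    def n_inputs(self) -> int:
        return self.W_zy.shape[0]

    @property
    def hidden(self) -> int:
        return self.W_zy.shape[1]

    @property
    def P(self) -> int:
        return self.head_W.shape[1]

    def as_dict(self) -> dict:
        return {
            "W_zy": self.W_zy,
            "W_zz": self.W_zz,
            "b": self.b,
            "head_W": self.head_W,
            "head_b": self.head_b,
        }


def init_rnn_params(n_inputs: int, hidden: int, P: int, seed: int = 0) -> RNNParams:
    """Fan-in-scaled uniform initialization, deterministic in the seed."""
    rng = np.random.default_rng(seed)
    return RNNParams(
        W_zy=_fan_in_uniform(rng, (n_inputs, hidden), n_inputs),
        W_zz=_fan_in_uniform(rng, (hidden, hidden), hidden),
        b=np.zeros(hidden, dtype=np.float32),
        head_W=_fan_in_uniform(rng, (hidden, P), hidden),
        head_b=np.zeros(P, dtype=np.float32),
    )


def rnn_forward(sequence: np.ndarray, params: RNNParams, cache: bool = False):
    """Run the cell over a sequence (Lt, Nx) or batch (B, Lt, Nx).

    Returns outputs of shape (..., Lt, P); with ``cache=True`` also the
    intermediates needed by :func:`rnn_backward`.
    """
    seq = np.asarray(sequence)
    single = seq.ndim == 2
    if single:
        seq = seq[None]
    batch, lt, nx = seq.shape
    if nx != params.n_inputs:
        raise InvalidParameterError(
            f"sequence vectors of length {nx}, expected {params.n_inputs}"
        )
    nn_w = params.hidden
    z = np.zeros((batch, nn_w), dtype=seq.dtype)
    zs = np.empty((batch, lt, nn_w), dtype=seq.dtype)
    pre = np.empty((batch, lt, nn_w), dtype=seq.dtype)
    for t in range(lt):
        a = seq[:, t, :] @ params.W_zy + z @ params.W_zz + params.b
        z = _nn.relu(a)
        pre[:, t] = a
        zs[:, t] = z
    outputs = zs @ params.head_W + params.head_b
    if single:
        outputs = outputs[0]
    if cache:
        return outputs, (seq, pre, zs)
    return outputs


def rnn_backward(dout: np.ndarray, caches, params: RNNParams) -> dict:
    """Backpropagation through time; dout has shape (B, Lt, P)."""
    seq, pre, zs = caches
    batch, lt, _ = seq.shape
    grads = {k: np.zeros_like(v) for k, v in params.as_dict().items()}
    grads["head_W"] = np.einsum("btn,btp->np", zs, dout, optimize=True)
    grads["head_b"] = dout.sum(axis=(0, 1))
    dz_next = np.zeros((batch, params.hidden), dtype=seq.dtype)
    for t in range(lt - 1, -1, -1):
        dz = dout[:, t] @ params.head_W.T + dz_next
        da = _nn.relu_backward(dz, pre[:, t])
        grads["W_zy"] += seq[:, t].T @ da
        z_prev = zs[:, t - 1] if t > 0 else np.zeros_like(dz_next)
        grads["W_zz"] += z_prev.T @ da
        grads["b"] += da.sum(axis=0)
        dz_next = da @ params.W_zz.T
    return grads


def predict_pixel(patch: np.ndarray, params: RNNParams) -> float:
    """Patch-to-pixel prediction: the last output step only (P must be 1)."""
    if params.P != 1:
        raise InvalidParameterError("predict_pixel requires a P=1 head")
    outputs = rnn_forward(patch, params)
    return float(outputs[-1, 0])


def predict_patch(patch: np.ndarray, params: RNNParams) -> np.ndarray:
    """Patch-to-patch prediction: all steps stacked to Lt x Nx (P == Nx)."""
    if params.P != params.n_inputs:
        raise InvalidParameterError("predict_patch requires a P=Nx head")
    return rnn_forward(patch, params)


# ---------------------------------------------------------------------------
# deblurring front end
# ---------------------------------------------------------------------------


def gaussian_kernel(size: int = 7, sigma: float = 1.0) -> np.ndarray:
    """Truncated 2D Gaussian, normalized to unit sum on the size x size grid."""
    half = size // 2
    k = np.arange(-half, half + 1)
    g1 = np.exp(-(k**2) / (2.0 * sigma**2))
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def deblur_preprocess(
    image: LogImage, size: int = 7, sigma: float = 1.0
) -> LogImage:
    """Low-pass the tomogram so the despeckler trains as a deblurrer."""
    if min(image.shape) <= size:
        raise InvalidParameterError("image smaller than the blur kernel")
    kernel = gaussian_kernel(size, sigma)
    blurred = nd_convolve(image.values, kernel, mode="reflect")
    return LogImage(
        values=blurred, pitches=image.pitches, dynamic_range=image.dynamic_range
    )


# ---------------------------------------------------------------------------
# patch discriminator
# ---------------------------------------------------------------------------


@dataclass
class DiscriminatorParams:
    """Two fully connected layers over the flattened Lt x Nx patch."""

    W1: np.ndarray  # (Lt*Nx, hidden)
    b1: np.ndarray
    W2: np.ndarray  # (hidden, 1)
    b2: np.ndarray

    def __post_init__(self) -> None:
        if self.W2.shape != (self.W1.shape[1], 1):
            raise InvalidParameterError("discriminator layer shapes inconsistent")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    def as_dict(self) -> dict:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}


def init_discriminator_params(
    patch_shape: tuple, hidden: int = 128, seed: int = 0
) -> DiscriminatorParams:
    rng = np.random.default_rng(seed)
    dim = int(np.prod(patch_shape))
    return DiscriminatorParams(
        W1=_fan_in_uniform(rng, (dim, hidden), dim),
        b1=np.zeros(hidden, dtype=np.float32),
        W2=_fan_in_uniform(rng, (hidden, 1), hidden),
        b2=np.zeros(1, dtype=np.float32),
    )


def _discriminator_logits(flat: np.ndarray, params: DiscriminatorParams):
    h_pre = flat @ params.W1 + params.b1
    h = _nn.relu(h_pre)
    logits = h @ params.W2 + params.b2
    return logits, h_pre, h


def discriminator_forward(patch: np.ndarray, params: DiscriminatorParams):
    """Realness score in (0, 1): flatten -> affine -> ReLU -> affine -> sigmoid.

    Accepts one patch (Lt, Nx) or a batch (B, Lt, Nx); returns a float or a
    (B,) vector accordingly.
    """
    arr = np.asarray(patch)
    single = arr.ndim == 2
    flat = arr.reshape(1 if single else arr.shape[0], -1)
    if flat.shape[1] != params.input_dim:
        raise InvalidParameterError(
            f"patch has {flat.shape[1]} entries, expected {params.input_dim}"
        )
    logits, _, _ = _discriminator_logits(flat, params)
    scores = _nn.sigmoid(logits)[:, 0]
    return float(scores[0]) if single else scores


def discriminator_backward(
    flat: np.ndarray, labels: np.ndarray, params: DiscriminatorParams
):
    """Mean BCE loss, parameter grads, and input grads for a flat batch."""
    logits, h_pre, h = _discriminator_logits(flat, params)
    loss = _nn.bce_with_logits(logits, labels)
    dlogits = _nn.bce_with_logits_backward(logits, labels)
    dh = dlogits @ params.W2.T
    dW2 = h.T @ dlogits
    db2 = dlogits.sum(axis=0)
    dh_pre = _nn.relu_backward(dh, h_pre)
    dW1 = flat.T @ dh_pre
    db1 = dh_pre.sum(axis=0)
    dflat = dh_pre @ params.W1.T
    grads = {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}
    return loss, grads, dflat


def discriminator_input_gradient(
    patch: np.ndarray, params: DiscriminatorParams, label: float = 1.0
) -> np.ndarray:
    """Gradient of the BCE(score, label) loss w.r.t. the input patch."""
    arr = np.asarray(patch, dtype=np.float64)
    flat = arr.reshape(1, -1)
    _, _, dflat = discriminator_backward(
        flat, np.full((1, 1), label), params
    )
    return dflat.reshape(arr.shape)


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------


@dataclass
class UNetParams:
    """Encoder–decoder convolutional weights with skip connections.

    ``depth`` pooling levels, ``base_channels`` at the first; channel count
    doubles per level.  The default (depth 4, base 32) lands at about
    7.8 million trainable scalars.
    """

    weights: dict
    depth: int = 4
    base_channels: int = 32

    def as_dict(self) -> dict:
        return self.weights


def _conv_shapes(depth: int, base: int, in_ch: int = 1, out_ch: int = 1):
    """Yield (name, shape, fan_in) for every parameter tensor."""
    chans = [base * 2**i for i in range(depth + 1)]
    prev = in_ch
    for i, c in enumerate(chans[:-1]):
        yield f"enc{i}_c1_W", (3, 3, prev, c), 9 * prev
        yield f"enc{i}_c1_b", (c,), 9 * prev
        yield f"enc{i}_c2_W", (3, 3, c, c), 9 * c
        yield f"enc{i}_c2_b", (c,), 9 * c
        prev = c
    cb = chans[-1]
    yield "bott_c1_W", (3, 3, prev, cb), 9 * prev
    yield "bott_c1_b", (cb,), 9 * prev
    yield "bott_c2_W", (3, 3, cb, cb), 9 * cb
    yield "bott_c2_b", (cb,), 9 * cb
    up_in = cb
    for i in range(depth - 1, -1, -1):
        c = chans[i]
        yield f"up{i}_W", (up_in, c, 2, 2), 4 * up_in
        yield f"up{i}_b", (c,), 4 * up_in
        yield f"dec{i}_c1_W", (3, 3, 2 * c, c), 9 * 2 * c
        yield f"dec{i}_c1_b", (c,), 9 * 2 * c
        yield f"dec{i}_c2_W", (3, 3, c, c), 9 * c
        yield f"dec{i}_c2_b", (c,), 9 * c
        up_in = c
    yield "final_W", (1, 1, chans[0], out_ch), chans[0]
    yield "final_b", (out_ch,), chans[0]


def init_unet_params(
    depth: int = 4, base_channels: int = 32, seed: int = 0
) -> UNetParams:
    rng = np.random.default_rng(seed)
    weights = {}
    for name, shape, fan_in in _conv_shapes(depth, base_channels):
        if name.endswith("_b"):
            weights[name] = np.zeros(shape, dtype=np.float32)
        else:
            weights[name] = _fan_in_uniform(rng, shape, fan_in)
    return UNetParams(weights=weights, depth=depth, base_channels=base_channels)


def _conv_relu(x, params, name, caches, want_cache):
    out, cols = _nn.conv2d(x, params.weights[name + "_W"], params.weights[name + "_b"])
    act = _nn.relu(out)
    if want_cache:
        caches[name] = (x.shape, cols, out)
    return act


def unet_forward(x: np.ndarray, params: UNetParams, cache: bool = False):
    """Forward pass on (B, H, W) or (B, H, W, 1); H and W must be multiples
    of ``2**depth``.  Output has the input's shape."""
    arr = np.asarray(x)
    squeeze_channel = arr.ndim == 3
    if squeeze_channel:
        arr = arr[..., None]
    batch, h, w, _ = arr.shape
    stride = 2**params.depth
    if h % stride or w % stride:
        raise InvalidParameterError(
            f"input sides must be multiples of {stride}; got {(h, w)}"
        )
    caches: dict = {}
    skips = []
    cur = arr
    for i in range(params.depth):
        cur = _conv_relu(cur, params, f"enc{i}_c1", caches, cache)
        cur = _conv_relu(cur, params, f"enc{i}_c2", caches, cache)
        skips.append(cur)
        cur, idx = _nn.maxpool2(cur)
        if cache:
            caches[f"pool{i}"] = (idx, skips[-1].shape)
    cur = _conv_relu(cur, params, "bott_c1", caches, cache)
    cur = _conv_relu(cur, params, "bott_c2", caches, cache)
    for i in range(params.depth - 1, -1, -1):
        up = _nn.conv_transpose2(cur, params.weights[f"up{i}_W"], params.weights[f"up{i}_b"])
        if cache:
            caches[f"up{i}"] = cur
        cur = np.concatenate([skips[i], up], axis=-1)
        cur = _conv_relu(cur, params, f"dec{i}_c1", caches, cache)
        cur = _conv_relu(cur, params, f"dec{i}_c2", caches, cache)
    out = (
        cur @ params.weights["final_W"][0, 0] + params.weights["final_b"]
    )
    if cache:
        caches["final"] = cur
    if squeeze_channel:
        out = out[..., 0]
    if cache:
        return out, caches
    return out


def unet_backward(dout: np.ndarray, caches: dict, params: UNetParams) -> dict:
    """Gradients for every U-Net parameter given d(loss)/d(output)."""
    darr = np.asarray(dout)
    if darr.ndim == 3:
        darr = darr[..., None]
    grads = {}
    w = params.weights

    final_in = caches["final"]
    grads["final_W"] = np.einsum(
        "bhwc,bhwo->co", final_in, darr, optimize=True
    )[None, None]
    grads["final_b"] = darr.sum(axis=(0, 1, 2))
    dcur = darr @ w["final_W"][0, 0].T

    def conv_relu_back(dact, name):
        x_shape, cols, pre = caches[name]
        dpre = _nn.relu_backward(dact, pre.reshape(dact.shape))
        dx, dW, db = _nn.conv2d_backward(dpre, cols, w[name + "_W"], x_shape)
        grads[name + "_W"] = dW
        grads[name + "_b"] = db
        return dx

    dskip_from_dec = {}
    for i in range(params.depth):
        dcur = conv_relu_back(dcur, f"dec{i}_c2")
        dcur = conv_relu_back(dcur, f"dec{i}_c1")
        c = params.base_channels * 2**i
        dskip_from_dec[i] = dcur[..., :c]
        dup = dcur[..., c:]
        up_in = caches[f"up{i}"]
        dcur, dW, db = _nn.conv_transpose2_backward(dup, up_in, w[f"up{i}_W"])
        grads[f"up{i}_W"] = dW
        grads[f"up{i}_b"] = db
    dcur = conv_relu_back(dcur, "bott_c2")
    dcur = conv_relu_back(dcur, "bott_c1")
    for i in range(params.depth - 1, -1, -1):
        idx, pre_pool_shape = caches[f"pool{i}"]
        dcur = _nn.maxpool2_backward(dcur, idx, pre_pool_shape)
        dcur = dcur + dskip_from_dec[i]
        dcur = conv_relu_back(dcur, f"enc{i}_c2")
        dcur = conv_relu_back(dcur, f"enc{i}_c1")
    return grads


# ---------------------------------------------------------------------------
# model container and bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class DespecklerModel:
    """A sealed trained predictor with everything inference needs."""

    method: str  # rnn | drnn | rnn_gan | unet
    params: object  # RNNParams | UNetParams
    patch_cfg: Optional[AnalysisPatchConfig]
    normalization: Optional[Normalization]
    source_spec: Optional[OCTSystemSpec] = None
    deblur_filter: Optional[tuple] = None  # (size, sigma) for drnn
    stride: tuple = (1, 1)  # patch-to-patch inference stride
    loss_trace: list = field(default_factory=list)
    n_crops_drawn: int = 0  # unet bookkeeping

    def __post_init__(self) -> None:
        if self.method not in ("rnn", "drnn", "rnn_gan", "unet"):
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if self.method == "drnn" and self.deblur_filter is None:
            raise InvalidParameterError("drnn model requires a deblur filter")
        if self.method in ("rnn", "drnn") and self.params.P != 1:
            raise InvalidParameterError("patch-to-pixel methods require P=1")
        if self.method == "rnn_gan" and self.params.P != self.params.n_inputs:
            raise InvalidParameterError("rnn_gan requires a patch head (P=Nx)")


def count_parameters(model) -> int:
    """Exact trainable scalar count of any parameter container."""
    if hasattr(model, "params"):
        model = model.params
    if hasattr(model, "as_dict"):
        model = model.as_dict()
    return int(sum(np.asarray(v).size for v in model.values()))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def model_manifest(model: DespecklerModel) -> dict:
    """JSON-serializable description of everything but the weights."""
    manifest: dict = {"method": model.method, "stride": list(model.stride)}
    if model.patch_cfg is not None:
        manifest["patch_cfg"] = {
            k: getattr(model.patch_cfg, k) for k in ("Lt", "Nx", "nL", "nR", "P")
        }
    if model.normalization is not None:
        manifest["normalization"] = {
            "lo": model.normalization.lo,
            "hi": model.normalization.hi,
        }
    if model.deblur_filter is not None:
        manifest["deblur_filter"] = list(model.deblur_filter)
    if isinstance(model.params, UNetParams):
        manifest["unet"] = {
            "depth": model.params.depth,
            "base_channels": model.params.base_channels,
        }
    if model.source_spec is not None:
        spec = model.source_spec
        manifest["source_spec"] = {
            "name": spec.name,
            "delta_z_um": spec.delta_z,
            "delta_x_um": spec.delta_x,
            "omega_z_um": spec.omega_z,
            "omega_x_um": spec.omega_x,
            "n_spectral": spec.n_spectral,
            "n_fft": spec.n_fft,
        }
    return manifest


def save_model(model: DespecklerModel, path) -> None:
    """Write weights plus a JSON manifest to one HDF5 checkpoint."""
    import json

    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["manifest"] = json.dumps(model_manifest(model), sort_keys=True)
        grp = fh.create_group("params")
        for key, arr in model.params.as_dict().items():
            grp.create_dataset(key, data=arr)


def load_model(path) -> DespecklerModel:
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        manifest = json.loads(fh.attrs["manifest"])
        arrays = {key: fh["params"][key][()] for key in fh["params"]}
    if "unet" in manifest:
        params: object = UNetParams(
            weights=arrays,
            depth=manifest["unet"]["depth"],
            base_channels=manifest["unet"]["base_channels"],
        )
    elif "W_zy" in arrays:
        params = RNNParams(**arrays)
    else:
        raise InvalidParameterError("unrecognized checkpoint contents")
    patch_cfg = (
        AnalysisPatchConfig(**manifest["patch_cfg"]) if "patch_cfg" in manifest else None
    )
    norm = (
        Normalization(**manifest["normalization"])
        if "normalization" in manifest
        else None
    )
    spec = (
        OCTSystemSpec.from_dict(manifest["source_spec"])
        if "source_spec" in manifest
        else None
    )
    return DespecklerModel(
        method=manifest["method"],
        params=params,
        patch_cfg=patch_cfg,
        normalization=norm,
        source_spec=spec,
        deblur_filter=tuple(manifest["deblur_filter"])
        if "deblur_filter" in manifest
        else None,
        stride=tuple(manifest["stride"]),
    )
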
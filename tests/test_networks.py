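"""Network forward/backward correctness against independent oracles."""

import math

import numpy as np
import pytest

from octshot import _nn, networks as nw
from octshot import patching as pt
from octshot import speckle_sim as ss
from octshot.system_model import InvalidParameterError


def _loop_rnn(seq, p):
    """Naive per-scalar recurrence, independent of the vectorized path."""
    lt, nx = seq.shape
    nn_w = p.hidden
    z = [0.0] * nn_w
    outputs = []
    for t in range(lt):
        a = []
        for j in range(nn_w):
            s = float(p.b[j])
            for i in range(nx):
                s += float(seq[t, i]) * float(p.W_zy[i, j])
            for k in range(nn_w):
                s += z[k] * float(p.W_zz[k, j])
            a.append(max(s, 0.0))
        z = a
        outputs.append(
            [
                sum(z[k] * float(p.head_W[k, q]) for k in range(nn_w))
                + float(p.head_b[q])
                for q in range(p.P)
            ]
        )
    return np.array(outputs)


def test_rnn_forward_matches_scalar_loop_oracle():
    """100 random small instances, elementwise to 1e-6 relative."""
    rng = np.random.default_rng(42)
    for case in range(100):
        lt = int(rng.integers(1, 5))
        nx = int(rng.integers(1, 4))
        hidden = int(rng.integers(1, 6))
        p_out = int(rng.integers(1, 4))
        params = nw.init_rnn_params(nx, hidden, p_out, seed=case)
        params = nw.RNNParams(
            **{k: v.astype(np.float64) for k, v in params.as_dict().items()}
        )
        seq = rng.normal(size=(lt, nx))
        got = nw.rnn_forward(seq, params)
        want = _loop_rnn(seq, params)
        np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)


def test_rnn_zero_weights_output_head_bias():
    params = nw.RNNParams(
        W_zy=np.zeros((3, 4)),
        W_zz=np.zeros((4, 4)),
        b=np.zeros(4),
        head_W=np.zeros((4, 2)),
        head_b=np.array([0.3, -0.7]),
    )
    out = nw.rnn_forward(np.random.default_rng(0).normal(size=(5, 3)), params)
    np.testing.assert_allclose(out, np.tile([0.3, -0.7], (5, 1)))


def test_rnn_without_recurrence_is_feedforward():
    """W_zz = 0 severs the recurrence: each step depends only on its input."""
    rng = np.random.default_rng(1)
    params = nw.init_rnn_params(3, 6, 2, seed=0)
    params.W_zz[:] = 0.0
    seq = rng.normal(size=(4, 3)).astype(np.float32)
    out = nw.rnn_forward(seq, params)
    perm = [2, 0, 3, 1]
    out_perm = nw.rnn_forward(seq[perm], params)
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-6)


def test_rnn_shape_mismatch_rejected():
    params = nw.init_rnn_params(3, 4, 1, seed=0)
    with pytest.raises(InvalidParameterError):
        nw.rnn_forward(np.zeros((5, 4)), params)


def test_predict_pixel_is_last_output():
    params = nw.init_rnn_params(5, 8, 1, seed=3)
    patch = np.random.default_rng(4).normal(size=(6, 5)).astype(np.float32)
    assert nw.predict_pixel(patch, params) == pytest.approx(
        float(nw.rnn_forward(patch, params)[-1, 0])
    )
    with pytest.raises(InvalidParameterError):
        nw.predict_pixel(patch, nw.init_rnn_params(5, 8, 5, seed=3))


def test_predict_patch_stacks_steps():
    params = nw.init_rnn_params(5, 8, 5, seed=3)
    patch = np.random.default_rng(4).normal(size=(6, 5)).astype(np.float32)
    out = nw.predict_patch(patch, params)
    assert out.shape == (6, 5)
    np.testing.assert_allclose(out, nw.rnn_forward(patch, params))
    with pytest.raises(InvalidParameterError):
        nw.predict_patch(patch, nw.init_rnn_params(5, 8, 1, seed=3))


def test_anchored_sweep_matches_sliding_window_oracle():
    """Pixel-by-pixel anchored prediction equals the vectorized image sweep."""
    from octshot.networks import DespecklerModel
    from octshot.training import despeckle_image

    rng = np.random.default_rng(5)
    image = ss.LogImage(values=rng.normal(size=(10, 10)))
    cfg = pt.AnalysisPatchConfig(Lt=3, Nx=3, P=1)
    params = nw.init_rnn_params(3, 6, 1, seed=6)
    model = DespecklerModel("rnn", params, cfg, None)
    swept = despeckle_image(image, model)

    norm = pt.Normalization.from_image(image)
    img01 = ss.LogImage(values=norm.apply(image.values))
    for i in range(10):
        for j in range(10):
            patch = pt.extract_analysis_patch(img01, i, j, cfg).astype(np.float32)
            expected = norm.invert(nw.predict_pixel(patch, params))
            assert swept.values[i, j] == pytest.approx(expected, rel=1e-5)


# ---------------------------------------------------------------------------
# deblurring front end
# ---------------------------------------------------------------------------


def test_deblur_constant_image_unchanged():
    image = ss.LogImage(values=np.full((32, 32), -17.5))
    out = nw.deblur_preprocess(image)
    np.testing.assert_allclose(out.values, -17.5, atol=1e-9)


def test_gaussian_kernel_matches_closed_form():
    kernel = nw.gaussian_kernel(7, 1.0)
    k = np.arange(-3, 4)
    direct = np.exp(-(k[:, None] ** 2 + k[None, :] ** 2) / 2.0)
    direct /= direct.sum()
    np.testing.assert_allclose(kernel, direct, rtol=1e-12)
    assert kernel.sum() == pytest.approx(1.0)
    assert kernel[3, 3] == kernel.max()


def test_deblur_reduces_noise_variance():
    rng = np.random.default_rng(8)
    image = ss.LogImage(values=rng.normal(size=(64, 64)))
    out = nw.deblur_preprocess(image)
    assert out.values.var() < 0.5 * image.values.var()


# ---------------------------------------------------------------------------
# discriminator
# ---------------------------------------------------------------------------


def test_discriminator_zero_weights_score_half():
    params = nw.DiscriminatorParams(
        W1=np.zeros((9, 8)), b1=np.zeros(8), W2=np.zeros((8, 1)), b2=np.zeros(1)
    )
    assert nw.discriminator_forward(np.ones((3, 3)), params) == 0.5


def test_discriminator_scores_in_unit_interval():
    params = nw.init_discriminator_params((15, 15), hidden=32, seed=0)
    batch = np.random.default_rng(9).normal(size=(50, 15, 15)).astype(np.float32) * 10
    scores = nw.discriminator_forward(batch, params)
    assert np.all((scores > 0) & (scores < 1))


def test_discriminator_input_gradient_matches_finite_differences():
    params = nw.init_discriminator_params((3, 3), hidden=8, seed=1)
    params = nw.DiscriminatorParams(
        **{k: v.astype(np.float64) for k, v in params.as_dict().items()}
    )
    x = np.random.default_rng(10).normal(size=(3, 3))
    grad = nw.discriminator_input_gradient(x, params, label=1.0)
    eps = 1e-6
    for i in range(3):
        for j in range(3):
            old = x[i, j]
            x[i, j] = old + eps
            lp = -math.log(nw.discriminator_forward(x, params))
            x[i, j] = old - eps
            lm = -math.log(nw.discriminator_forward(x, params))
            x[i, j] = old
            num = (lp - lm) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, rel=1e-4, abs=1e-9)


def test_discriminator_shape_mismatch_rejected():
    params = nw.init_discriminator_params((15, 15), hidden=8)
    with pytest.raises(InvalidParameterError):
        nw.discriminator_forward(np.zeros((4, 4)), params)


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------


def test_unet_preserves_shape():
    params = nw.init_unet_params(depth=2, base_channels=4, seed=0)
    for size in ((1, 64, 64), (2, 16, 32)):
        x = np.random.default_rng(11).normal(size=size).astype(np.float32)
        assert nw.unet_forward(x, params).shape == x.shape


def test_unet_rejects_unaligned_sides():
    params = nw.init_unet_params(depth=3, base_channels=4, seed=0)
    with pytest.raises(InvalidParameterError):
        nw.unet_forward(np.zeros((1, 20, 64), dtype=np.float32), params)


def test_unet_zero_final_layer_outputs_bias():
    params = nw.init_unet_params(depth=2, base_channels=4, seed=0)
    params.weights["final_W"][:] = 0.0
    params.weights["final_b"][:] = -0.25
    x = np.random.default_rng(12).normal(size=(1, 16, 16)).astype(np.float32)
    np.testing.assert_allclose(nw.unet_forward(x, params), -0.25, atol=1e-7)


def test_unet_gradients_match_finite_differences():
    rng = np.random.default_rng(13)
    params = nw.init_unet_params(depth=2, base_channels=3, seed=4)
    params = nw.UNetParams(
        {k: v.astype(np.float64) for k, v in params.weights.items()},
        depth=2,
        base_channels=3,
    )
    x = rng.normal(size=(2, 8, 8))
    target = rng.normal(size=(2, 8, 8))

    out, cache = nw.unet_forward(x, params, cache=True)
    grads = nw.unet_backward(out - target, cache, params)

    eps = 1e-6
    for key, arr in params.weights.items():
        flat = arr.reshape(-1)
        for idx in rng.choice(arr.size, size=min(3, arr.size), replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            lp = 0.5 * np.sum((nw.unet_forward(x, params) - target) ** 2)
            flat[idx] = old - eps
            lm = 0.5 * np.sum((nw.unet_forward(x, params) - target) ** 2)
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            assert grads[key].reshape(-1)[idx] == pytest.approx(
                num, rel=1e-4, abs=1e-7
            ), key


# ---------------------------------------------------------------------------
# low-level kernels
# ---------------------------------------------------------------------------


def test_conv2d_gradients_match_finite_differences():
    rng = np.random.default_rng(14)
    x = rng.normal(size=(2, 5, 6, 3))
    W = rng.normal(size=(3, 3, 3, 2))
    b = rng.normal(size=2)
    target = rng.normal(size=(2, 5, 6, 2))
    out, cols = _nn.conv2d(x, W, b)
    dx, dW, db = _nn.conv2d_backward(out - target, cols, W, x.shape)
    eps = 1e-6

    def loss():
        return 0.5 * np.sum((_nn.conv2d(x, W, b)[0] - target) ** 2)

    for arr, grad in ((x, dx), (W, dW), (b, db)):
        flat = arr.reshape(-1)
        for idx in rng.choice(arr.size, size=min(5, arr.size), replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            lp = loss()
            flat[idx] = old - eps
            lm = loss()
            flat[idx] = old
            assert grad.reshape(-1)[idx] == pytest.approx(
                (lp - lm) / (2 * eps), rel=1e-5, abs=1e-8
            )


def test_maxpool_and_transpose_conv_gradients():
    rng = np.random.default_rng(15)
    x = rng.normal(size=(2, 4, 4, 3))
    out, idx = _nn.maxpool2(x)
    dout = rng.normal(size=out.shape)
    dx = _nn.maxpool2_backward(dout, idx, x.shape)
    eps = 1e-6
    flat = x.reshape(-1)
    for i in rng.choice(x.size, size=8, replace=False):
        old = flat[i]
        flat[i] = old + eps
        lp = np.sum(_nn.maxpool2(x)[0] * dout)
        flat[i] = old - eps
        lm = np.sum(_nn.maxpool2(x)[0] * dout)
        flat[i] = old
        assert dx.reshape(-1)[i] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)

    W = rng.normal(size=(3, 2, 2, 2))
    b = rng.normal(size=2)
    y = _nn.conv_transpose2(x, W, b)
    assert y.shape == (2, 8, 8, 2)
    dy = rng.normal(size=y.shape)
    dx, dW, db = _nn.conv_transpose2_backward(dy, x, W)
    for arr, grad in ((x, dx), (W, dW), (b, db)):
        flat = arr.reshape(-1)
        for i in rng.choice(arr.size, size=min(5, arr.size), replace=False):
            old = flat[i]
            flat[i] = old + eps
            lp = np.sum(_nn.conv_transpose2(x, W, b) * dy)
            flat[i] = old - eps
            lm = np.sum(_nn.conv_transpose2(x, W, b) * dy)
            flat[i] = old
            assert grad.reshape(-1)[i] == pytest.approx(
                (lp - lm) / (2 * eps), rel=1e-5, abs=1e-6
            )


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------


def test_default_rnn_parameter_count():
    params = nw.init_rnn_params(15, 1000, 15, seed=0)
    assert nw.count_parameters(params) == 15 * 1000 + 1000 * 1000 + 1000 + 1000 * 15 + 15
    assert nw.count_parameters(params) == 1_031_015


def test_degenerate_rnn_parameter_count():
    assert nw.count_parameters(nw.init_rnn_params(1, 1, 1, seed=0)) == 5


def test_discriminator_parameter_count():
    lt, nx, hidden = 15, 15, 128
    params = nw.init_discriminator_params((lt, nx), hidden=hidden)
    assert nw.count_parameters(params) == (lt * nx + 1) * hidden + (hidden + 1)


def test_default_unet_parameter_count_near_target():
    count = nw.count_parameters(nw.init_unet_params())
    assert abs(count - 8.2e6) / 8.2e6 < 0.25


def test_rnn_and_drnn_share_architecture():
    """The deblurring variant differs only in preprocessing, not in shape."""
    a = nw.init_rnn_params(15, 64, 1, seed=0)
    b = nw.init_rnn_params(15, 64, 1, seed=0)
    assert {k: v.shape for k, v in a.as_dict().items()} == {
        k: v.shape for k, v in b.as_dict().items()
    }
    np.testing.assert_array_equal(a.W_zy, b.W_zy)


def test_forward_passes_are_deterministic():
    params = nw.init_rnn_params(5, 16, 1, seed=0)
    patch = np.random.default_rng(16).normal(size=(6, 5)).astype(np.float32)
    np.testing.assert_array_equal(
        nw.rnn_forward(patch, params), nw.rnn_forward(patch, params)
    )
    unet = nw.init_unet_params(depth=2, base_channels=4, seed=0)
    x = np.random.default_rng(17).normal(size=(1, 16, 16)).astype(np.float32)
    np.testing.assert_array_equal(nw.unet_forward(x, unet), nw.unet_forward(x, unet))
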
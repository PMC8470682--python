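"""The CNN engine against brute-force oracles and numerical gradients.

The forward rules under test are the classic ones: a convolution is the
double sum over the kernel support with the kernel flipped, batch
normalisation standardises per channel with trainable scale/shift, ReLU
clamps negatives, max pooling emits windowed maxima with output dims
floor((D - n)/stride) + 1.
"""

import numpy as np
import pytest

from polypnet.nn import (
    Adam,
    BatchNorm2D,
    Dense,
    Flatten,
    MaxPool2D,
    MultiKernelConv2D,
    PointwiseConv2D,
    ReLU,
    Sequential,
)
from polypnet.nn.ops import conv2d_same, max_pool, sigmoid, softmax


def conv_oracle(x, w):
    """Brute-force double sum: out(y, x) = sum_p sum_q I(p,q) K(y-p+1, x-q+1).

    Evaluated per output pixel with the kernel flipped, 'same' zero
    padding; independent of the GEMM path.
    """
    n, h, wd, cin = x.shape
    kh, kw, _, cout = w.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((n, h, wd, cout))
    for b in range(n):
        for yy in range(h):
            for xx in range(wd):
                for co in range(cout):
                    acc = 0.0
                    for p in range(-ph, ph + 1):
                        for q in range(-pw, pw + 1):
                            iy, ix = yy + p, xx + q
                            if 0 <= iy < h and 0 <= ix < wd:
                                for ci in range(cin):
                                    # flipped kernel indexing
                                    acc += x[b, iy, ix, ci] * w[ph - p, pw - q, ci, co]
                    out[b, yy, xx, co] = acc
    return out


def pool_oracle(x, size, stride):
    n, h, w, c = x.shape
    ho = (h - size) // stride + 1
    wo = (w - size) // stride + 1
    out = np.zeros((n, ho, wo, c))
    for b in range(n):
        for i in range(ho):
            for j in range(wo):
                win = x[b, i * stride : i * stride + size, j * stride : j * stride + size, :]
                out[b, i, j] = win.max(axis=(0, 1))
    return out


class TestConvolution:
    def test_centered_delta_is_identity(self, rng):
        x = rng.normal(size=(1, 6, 6, 1)).astype(np.float32)
        w = np.zeros((3, 3, 1, 1), dtype=np.float32)
        w[1, 1, 0, 0] = 1.0
        assert np.allclose(conv2d_same(x, w), x, atol=1e-6)

    def test_zero_input_zero_output(self, rng):
        w = rng.normal(size=(3, 3, 2, 4)).astype(np.float32)
        y = conv2d_same(np.zeros((2, 5, 5, 2), dtype=np.float32), w)
        assert (y == 0).all()

    def test_matches_double_sum_oracle(self, rng):
        x = rng.normal(size=(1, 8, 8, 1)).astype(np.float32)
        w = rng.normal(size=(3, 3, 1, 2)).astype(np.float32)
        assert np.allclose(conv2d_same(x, w), conv_oracle(x, w), atol=1e-5)

    @pytest.mark.parametrize("shape", [(3, 3), (3, 1), (1, 3)])
    def test_each_kernel_shape_matches_oracle(self, rng, shape):
        x = rng.normal(size=(2, 6, 7, 3)).astype(np.float32)
        w = rng.normal(size=(*shape, 3, 2)).astype(np.float32)
        assert np.allclose(conv2d_same(x, w), conv_oracle(x, w), atol=1e-5)

    def test_multi_kernel_block_is_sum_of_three_branches(self, rng):
        """The (3x3 + 3x1 + 1x3) block equals the three parallel
        convolutions evaluated independently and summed elementwise."""
        layer = MultiKernelConv2D(2, 3, rng)
        x = rng.normal(size=(1, 8, 8, 2)).astype(np.float32)
        expected = (
            conv_oracle(x, layer.params["w33"])
            + conv_oracle(x, layer.params["w31"])
            + conv_oracle(x, layer.params["w13"])
        )
        assert np.allclose(layer.forward(x), expected, atol=1e-5)


class TestBatchNorm:
    def test_standardised_batch_passes_through(self, rng):
        bn = BatchNorm2D(3)
        x = rng.normal(size=(8, 4, 4, 3)).astype(np.float32)
        x = (x - x.mean(axis=(0, 1, 2))) / x.std(axis=(0, 1, 2))
        y = bn.forward(x.astype(np.float32), training=True)
        assert np.allclose(y, x, atol=1e-3)

    def test_constant_batch_maps_to_beta(self):
        bn = BatchNorm2D(2)
        bn.params["beta"] = np.array([1.5, -2.0], dtype=np.float32)
        x = np.full((4, 3, 3, 2), 7.0, dtype=np.float32)
        y = bn.forward(x, training=True)
        assert np.allclose(y[..., 0], 1.5, atol=1e-4)
        assert np.allclose(y[..., 1], -2.0, atol=1e-4)

    def test_matches_scalar_oracle(self, rng):
        bn = BatchNorm2D(2, eps=1e-5)
        bn.params["gamma"] = np.array([2.0, 0.5], dtype=np.float32)
        bn.params["beta"] = np.array([-1.0, 3.0], dtype=np.float32)
        x = rng.normal(size=(4, 3, 5, 2)).astype(np.float32)
        y = bn.forward(x, training=True)
        for ch in range(2):
            mu = x[..., ch].mean()
            var = x[..., ch].var()
            expected = bn.params["gamma"][ch] * (x[..., ch] - mu) / np.sqrt(var + 1e-5) + bn.params["beta"][ch]
            assert np.allclose(y[..., ch], expected, atol=1e-4)


class TestReLUAndPool:
    def test_relu_clamps_negatives(self, rng):
        x = -np.abs(rng.normal(size=(2, 4, 4, 3))).astype(np.float32)
        assert (ReLU().forward(x) == 0).all()

    def test_pool_quadrant_maxima(self, rng):
        x = rng.normal(size=(1, 4, 4, 1)).astype(np.float32)
        y = max_pool(x, 2, 2)
        assert y.shape == (1, 2, 2, 1)
        assert np.allclose(y, pool_oracle(x, 2, 2))

    @pytest.mark.parametrize("size,stride,din,dout", [(2, 2, 128, 64), (2, 3, 120, 40), (2, 3, 13, 4)])
    def test_output_dims(self, rng, size, stride, din, dout):
        x = rng.normal(size=(1, din, din, 1)).astype(np.float32)
        assert max_pool(x, size, stride).shape[1] == dout

    def test_stride_three_matches_oracle(self, rng):
        x = rng.normal(size=(2, 11, 13, 3)).astype(np.float32)
        assert np.allclose(max_pool(x, 2, 3), pool_oracle(x, 2, 3))

    def test_window_larger_than_input_rejected(self):
        with pytest.raises(ValueError, match="window"):
            max_pool(np.zeros((1, 3, 3, 1), dtype=np.float32), 4, 1)


class TestActivations:
    def test_softmax_sums_to_one_and_shift_invariant(self, rng):
        z = rng.normal(size=(5, 2)) * 10
        p = softmax(z, axis=1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(softmax(z + 123.0, axis=1), p, atol=1e-9)

    def test_sigmoid_extremes_are_stable(self):
        z = np.array([-800.0, 0.0, 800.0])
        s = sigmoid(z)
        assert s[0] == 0.0 and s[1] == 0.5 and s[2] == 1.0


class TestGradients:
    """Analytic backward passes against central finite differences."""

    def _model(self, rng):
        return Sequential(
            [
                ("conv", MultiKernelConv2D(2, 3, rng)),
                ("bn", BatchNorm2D(3)),
                ("relu", ReLU()),
                ("pool", MaxPool2D(2, 2)),
                ("head", PointwiseConv2D(3, 2, rng)),
                ("flatten", Flatten()),
                ("fc", Dense(2 * 3 * 3, 2, rng)),
            ]
        )

    def test_parameter_gradients_match_finite_differences(self, rng):
        model = self._model(rng)
        x = rng.normal(size=(2, 6, 6, 2)).astype(np.float32)
        tgt = rng.normal(size=(2, 2)).astype(np.float32)

        def loss():
            y = model.forward(x, training=True)
            return 0.5 * float(((y - tgt) ** 2).sum()), (y - tgt)

        _, g = loss()
        model.backward(g)
        for name, layer, pname in model.named_params():
            p = layer.params[pname]
            analytic = layer.grads[pname]
            for _ in range(3):
                idx = tuple(int(rng.integers(0, s)) for s in p.shape)
                eps = 1e-3
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = loss()
                p[idx] = orig - eps
                lm, _ = loss()
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - analytic[idx]) < 1e-2 * max(1.0, abs(numeric)), name

    def test_input_gradient_matches_finite_differences(self, rng):
        model = self._model(rng)
        x = rng.normal(size=(1, 6, 6, 2)).astype(np.float32)
        tgt = rng.normal(size=(1, 2)).astype(np.float32)

        def loss(inp):
            y = model.forward(inp, training=True)
            return 0.5 * float(((y - tgt) ** 2).sum()), (y - tgt)

        _, g = loss(x)
        gx = model.backward(g)
        for _ in range(5):
            idx = tuple(int(rng.integers(0, s)) for s in x.shape)
            eps = 1e-3
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            numeric = (loss(xp)[0] - loss(xm)[0]) / (2 * eps)
            assert abs(numeric - gx[idx]) < 1e-2 * max(1.0, abs(numeric))


def test_adam_reduces_quadratic_loss(rng):
    model = Sequential([("fc", Dense(4, 1, rng))])
    opt = Adam(model, lr=0.05)
    x = rng.normal(size=(16, 4)).astype(np.float32)
    w_true = np.array([[1.0], [-2.0], [0.5], [3.0]], dtype=np.float32)
    y = x @ w_true
    first = last = None
    for _ in range(200):
        pred = model.forward(x, training=True)
        loss = float(((pred - y) ** 2).mean())
        model.backward(2 * (pred - y) / len(x))
        opt.step()
        first = loss if first is None else first
        last = loss
    assert last < 1e-2 * first
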
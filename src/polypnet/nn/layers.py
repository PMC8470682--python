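"""Trainable layers and the sequential container.

The layer set is exactly what the two polyp-CNN architectures need:
a multi-kernel convolution block (parallel 3x3, 3x1 and 1x3 kernels whose
responses are summed), batch normalisation, ReLU, max pooling, a 1x1
convolution head and a dense layer.  Each layer implements ``forward`` and
``backward`` explicitly; gradients are accumulated into ``grads`` keyed
like ``params``.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import ops


class Layer:
    """Base class: stateless by default, subclasses add params/caches."""

    def __init__(self) -> None:
        self.params: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.grads: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, shape: tuple) -> tuple:
        """Spatial bookkeeping for architecture audits; shape is (h, w, c)."""
        return shape

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _embed_3x3(w33: np.ndarray, w31: np.ndarray, w13: np.ndarray) -> np.ndarray:
    """Sum the three parallel kernels into one effective 3x3 kernel.

    A same-padded 3x1 (or 1x3) convolution equals a 3x3 convolution whose
    off-column (off-row) taps are zero, so the sum of the three parallel
    branches collapses to a single 3x3 sliding product — one GEMM pass
    instead of three, with identical output.
    """
    we = w33.copy()
    we[:, 1] += w31[:, 0]
    we[1, :] += w13[0, :]
    return we


class MultiKernelConv2D(Layer):
    """Parallel (3x3 + 3x1 + 1x3) convolution branches, summed elementwise.

    Each branch has its own kernel producing ``cout`` channels; branch
    outputs are added, so the block's channel count equals ``cout`` — the
    only combination rule consistent with the architecture tables, where a
    multi-kernel layer with N filters emits exactly N channels.  A
    concatenate-then-project variant is available via ``combine="project"``.
    No additive bias: every instance in these nets is followed by batch
    normalisation, whose shift parameter absorbs it.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator,
        combine: str = "sum",
    ) -> None:
        super().__init__()
        if combine not in ("sum", "project"):
            raise ValueError("combine must be 'sum' or 'project'")
        self.cin, self.cout, self.combine = cin, cout, combine
        std = np.sqrt(2.0 / (9 * cin))

        def init(shape):
            return rng.normal(0.0, std, size=shape).astype(np.float32)

        self.params["w33"] = init((3, 3, cin, cout))
        self.params["w31"] = init((3, 1, cin, cout))
        self.params["w13"] = init((1, 3, cin, cout))
        if combine == "project":
            pstd = np.sqrt(2.0 / (3 * cout))
            self.params["wproj"] = rng.normal(0.0, pstd, size=(3 * cout, cout)).astype(
                np.float32
            )
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x if training else None
        if self.combine == "sum":
            we = _embed_3x3(self.params["w33"], self.params["w31"], self.params["w13"])
            return ops.conv2d_same(x, we)
        branches = [
            ops.conv2d_same(x, self.params["w33"]),
            ops.conv2d_same(
                x, _embed_3x3(np.zeros_like(self.params["w33"]), self.params["w31"], np.zeros_like(self.params["w13"]))
            ),
            ops.conv2d_same(
                x, _embed_3x3(np.zeros_like(self.params["w33"]), np.zeros_like(self.params["w31"]), self.params["w13"])
            ),
        ]
        cat = np.concatenate(branches, axis=-1)
        self._cat = cat if training else None
        return ops.conv1x1(cat, self.params["wproj"])

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        if x is None:
            raise RuntimeError("backward called without a training forward pass")
        if self.combine == "sum":
            we = _embed_3x3(self.params["w33"], self.params["w31"], self.params["w13"])
            gx, gwe = ops.conv2d_same_backward(x, we, gy)
            # The embedding is linear, so branch gradients are slices of gwe.
            self.grads["w33"] = gwe
            self.grads["w31"] = gwe[:, 1:2].copy()
            self.grads["w13"] = gwe[1:2, :].copy()
            return gx
        cat = self._cat
        n, h, w, _ = cat.shape
        self.grads["wproj"] = cat.reshape(-1, 3 * self.cout).T @ gy.reshape(-1, self.cout)
        gcat = (gy.reshape(-1, self.cout) @ self.params["wproj"].T).reshape(cat.shape)
        g33, g31, g13 = np.split(gcat, 3, axis=-1)
        gx1, gw33 = ops.conv2d_same_backward(x, self.params["w33"], g33)
        w31e = _embed_3x3(np.zeros_like(self.params["w33"]), self.params["w31"], np.zeros_like(self.params["w13"]))
        gx2, gw31e = ops.conv2d_same_backward(x, w31e, g31)
        w13e = _embed_3x3(np.zeros_like(self.params["w33"]), np.zeros_like(self.params["w31"]), self.params["w13"])
        gx3, gw13e = ops.conv2d_same_backward(x, w13e, g13)
        self.grads["w33"] = gw33
        self.grads["w31"] = gw31e[:, 1:2].copy()
        self.grads["w13"] = gw13e[1:2, :].copy()
        return gx1 + gx2 + gx3

    def output_shape(self, shape: tuple) -> tuple:
        h, w, _ = shape
        return (h, w, self.cout)


class PointwiseConv2D(Layer):
    """1x1 convolution with bias — the detector's 24-channel head."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.params["w"] = rng.normal(0.0, std, size=(cin, cout)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x if training else None
        return ops.conv1x1(x, self.params["w"], self.params["b"])

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        gyf = gy.reshape(-1, self.cout)
        self.grads["w"] = x.reshape(-1, self.cin).T @ gyf
        self.grads["b"] = gyf.sum(axis=0)
        return (gyf @ self.params["w"].T).reshape(x.shape)

    def output_shape(self, shape: tuple) -> tuple:
        h, w, _ = shape
        return (h, w, self.cout)


class BatchNorm2D(Layer):
    """Per-channel batch normalisation over (batch, height, width).

    y = gamma * (x - mu) / sqrt(var + eps) + beta, with eps = 1e-5.
    Batch statistics are used in training; exponential running averages
    (momentum 0.9) at inference.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self.buffers["running_var"] = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.buffers["running_mean"] = (
                m * self.buffers["running_mean"] + (1 - m) * mu
            ).astype(np.float32)
            self.buffers["running_var"] = (
                m * self.buffers["running_var"] + (1 - m) * var
            ).astype(np.float32)
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if training:
            self._cache = (xhat, inv.astype(np.float32))
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (0, 1, 2)
        self.grads["gamma"] = (gy * xhat).sum(axis=axes)
        self.grads["beta"] = gy.sum(axis=axes)
        gscaled = gy * self.params["gamma"]
        mean_g = gscaled.mean(axis=axes)
        mean_gx = (gscaled * xhat).mean(axis=axes)
        return ((gscaled - mean_g - xhat * mean_gx) * inv).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2D(Layer):
    """size x size windowed maximum; output dims floor((D-size)/stride)+1."""

    def __init__(self, size: int = 2, stride: int = 2) -> None:
        super().__init__()
        self.size, self.stride = size, stride

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x)
        y = ops.max_pool(x, self.size, self.stride)
        if training:
            self._cache = (x, y)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, y = self._cache
        return ops.max_pool_backward(x, y, gy, self.size, self.stride)

    def output_shape(self, shape: tuple) -> tuple:
        h, w, c = shape
        return ((h - self.size) // self.stride + 1, (w - self.size) // self.stride + 1, c)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)

    def output_shape(self, shape: tuple) -> tuple:
        h, w, c = shape
        return (h * w * c,)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.nin, self.nout = nin, nout
        std = np.sqrt(2.0 / nin)
        self.params["w"] = rng.normal(0.0, std, size=(nin, nout)).astype(np.float32)
        self.params["b"] = np.zeros(nout, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x if training else None
        return x @ self.params["w"] + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["w"].T

    def output_shape(self, shape: tuple) -> tuple:
        return (self.nout,)


class Sequential:
    """Ordered layer stack with shape auditing and flat state (de)serialisation."""

    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for _, layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def shape_trace(self, input_shape: tuple) -> list[tuple[str, tuple]]:
        """Per-layer output shapes for a given (h, w, c) input."""
        trace = [("input", input_shape)]
        shape = input_shape
        for name, layer in self.layers:
            shape = layer.output_shape(shape)
            trace.append((name, shape))
        return trace

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for _, layer in self.layers)

    def named_params(self):
        for name, layer in self.layers:
            for pname, p in layer.params.items():
                yield f"{name}.{pname}", layer, pname

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        state: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for name, layer in self.layers:
            for pname, p in layer.params.items():
                state[f"{name}.{pname}"] = p
            for bname, b in layer.buffers.items():
                state[f"{name}.{bname}"] = b
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, layer in self.layers:
            for pname in layer.params:
                layer.params[pname] = np.asarray(state[f"{name}.{pname}"], dtype=np.float32)
            for bname in layer.buffers:
                layer.buffers[bname] = np.asarray(state[f"{name}.{bname}"], dtype=np.float32)

    def manifest(self, input_shape: tuple) -> str:
        """Human/machine-readable layer listing: name, output shape, #params."""
        lines = ["layer\toutput_shape\tn_params"]
        shape = input_shape
        for name, layer in self.layers:
            shape = layer.output_shape(shape)
            dims = "x".join(str(d) for d in shape)
            lines.append(f"{name}\t{dims}\t{layer.n_params}")
        lines.append(f"total\t-\t{self.n_params}")
        return "\n".join(lines) + "\n"
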
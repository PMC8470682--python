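"""Two-class polyp CNN: neoplastic versus hyperplastic.

Six multi-kernel convolution blocks with max pooling take a 480x640 frame
down to a 2x3x64 feature map (480x640 -> 240x320 -> 120x160 -> 40x53 ->
13x18 -> 4x6 -> 2x3; the middle pools use 2x2 windows at stride 3), which
a fully-connected layer maps to two logits and a softmax.  A frame is
called neoplastic when its softmax neoplastic probability reaches the 0.5
cutoff; the exact-0.5 tie resolves to neoplastic, the clinically
conservative direction.

The published layer table lists the final pool as "2x2/1", but 4x6 -> 2x3
is only achievable at stride 2; the printed output shape is taken as
binding and stride 2 is used.  The input row is read as H x W of the
landscape 640x480 frame; portrait inputs are transposed, never stretched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import prepare_image, recalibrate_batchnorm
from .nn import (
    Adam,
    BatchNorm2D,
    Dense,
    Flatten,
    MaxPool2D,
    MultiKernelConv2D,
    ReLU,
    Sequential,
)
from .nn.ops import softmax

INPUT_HW = (480, 640)  # (h, w)
CLASSIFICATION_CUTOFF = 0.5
CLASS_NAMES = ("neoplastic", "hyperplastic")  # logit order


@dataclass(frozen=True)
class ClassDecision:
    """Predicted label with the softmax score of the predicted class."""

    label: str
    probability: float
    p_neoplastic: float


@dataclass
class ClassifierConfig:
    in_channels: int = 1
    epochs: int = 10
    batch_size: int = 8
    lr: float = 1e-3
    cutoff: float = CLASSIFICATION_CUTOFF
    input_hw: tuple[int, int] = INPUT_HW
    combine: str = "sum"
    grayscale_mode: str = "standard"
    val_fraction: float = 0.2
    class_weighting: bool = True


# (filters, pool stride) per block; every pool window is 2x2
_BLOCKS = ((16, 2), (16, 2), (32, 3), (32, 3), (64, 3), (64, 2))


def build_classifier(
    in_channels: int,
    seed: int = 0,
    input_hw: tuple[int, int] = INPUT_HW,
    combine: str = "sum",
) -> Sequential:
    """Assemble the classification network for the given input size.

    The dense layer's fan-in is derived from the actual pooled feature-map
    size, so reduced-resolution experiments reuse the same topology.
    """
    if in_channels not in (1, 3):
        raise ValueError("in_channels must be 1 (grayscale) or 3 (color)")
    rng = np.random.default_rng(seed)
    layers: list = []
    c = in_channels
    shape = (input_hw[0], input_hw[1], c)
    for i, (cout, stride) in enumerate(_BLOCKS, start=1):
        layers.append((f"conv{i}", MultiKernelConv2D(c, cout, rng, combine=combine)))
        layers.append((f"bn{i}", BatchNorm2D(cout)))
        layers.append((f"relu{i}", ReLU()))
        layers.append((f"pool{i}", MaxPool2D(2, stride)))
        c = cout
    stack = Sequential(layers)
    shape = stack.shape_trace(shape)[-1][1]
    n_feat = shape[0] * shape[1] * shape[2]
    layers.append(("flatten", Flatten()))
    layers.append(("fc", Dense(n_feat, 2, rng)))
    return Sequential(layers)


def _orient(img: np.ndarray) -> np.ndarray:
    """Transpose portrait frames so height <= width (no stretching)."""
    if img.shape[0] > img.shape[1]:
        return np.swapaxes(img, 0, 1)
    return img


def classify(
    image: np.ndarray,
    model: Sequential,
    cutoff: float = CLASSIFICATION_CUTOFF,
    grayscale_mode: str = "standard",
    input_hw: tuple[int, int] = INPUT_HW,
) -> ClassDecision:
    """Predict neoplastic vs hyperplastic for one frame.

    Label = neoplastic iff softmax(neoplastic) >= cutoff.  ``input_hw``
    must match the size the model was built for.
    """
    in_channels = model.layers[0][1].cin
    x = prepare_image(_orient(image), in_channels, input_hw, grayscale_mode)
    logits = model.forward(x[None], training=False)[0]
    p = softmax(logits)
    p_neo = float(p[0])
    label = CLASS_NAMES[0] if p_neo >= cutoff else CLASS_NAMES[1]
    prob = p_neo if label == CLASS_NAMES[0] else float(p[1])
    return ClassDecision(label=label, probability=prob, p_neoplastic=p_neo)


def predict_proba(model: Sequential, xs: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Chunked inference: softmax class probabilities for prepared inputs."""
    out = []
    for start in range(0, len(xs), batch_size):
        logits = model.forward(xs[start : start + batch_size], training=False)
        out.append(softmax(logits, axis=1))
    return np.concatenate(out, axis=0)


def train_classifier(
    dataset: list[tuple[np.ndarray, str]],
    config: ClassifierConfig,
    seed: int,
) -> tuple[Sequential, str]:
    """Train on (frame, label) pairs with an internal 80/20 verify split.

    Cross-entropy with optional inverse-frequency class weights (the
    clinical verification splits are imbalanced); seed-reproducible.
    """
    labels = [lab for _, lab in dataset]
    if len(set(labels)) < 2:
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(seed)
    model = build_classifier(
        config.in_channels,
        seed=int(rng.integers(2**31)),
        input_hw=config.input_hw,
        combine=config.combine,
    )
    opt = Adam(model, lr=config.lr)

    xs = np.stack(
        [
            prepare_image(_orient(img), config.in_channels, config.input_hw, config.grayscale_mode)
            for img, _ in dataset
        ]
    )
    ys = np.array([CLASS_NAMES.index(lab) for lab in labels], dtype=int)

    n = len(dataset)
    perm = rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(set(ys[train_idx])) < 2:  # degenerate split on tiny data
        train_idx = perm
    if config.class_weighting:
        counts = np.bincount(ys[train_idx], minlength=2).astype(np.float64)
        weights = counts.sum() / (2.0 * np.maximum(counts, 1.0))
    else:
        weights = np.ones(2)

    lines = [
        f"n={n} train={len(train_idx)} verify={len(val_idx)} epochs={config.epochs} "
        f"batch={config.batch_size} lr={config.lr} weights={weights[0]:.4f},{weights[1]:.4f}"
    ]
    for epoch in range(1, config.epochs + 1):
        order = train_idx[rng.permutation(len(train_idx))]
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(xs[idx], training=True)
            p = softmax(logits, axis=1)
            y = ys[idx]
            wy = weights[y]
            eps = 1e-12
            loss = float(-(wy * np.log(p[np.arange(len(y)), y] + eps)).mean())
            grad = p.copy()
            grad[np.arange(len(y)), y] -= 1.0
            grad *= wy[:, None] / len(y)
            model.backward(grad.astype(np.float32))
            opt.step()
            losses.append(loss)
        recalibrate_batchnorm(model, xs[train_idx], config.batch_size)
        line = f"epoch={epoch} loss={np.mean(losses):.6f}"
        if len(val_idx):
            pv = predict_proba(model, xs[val_idx], config.batch_size)
            acc = float((pv.argmax(axis=1) == ys[val_idx]).mean())
            line += f" verify_acc={acc:.4f}"
        lines.append(line)
    return model, "\n".join(lines) + "\n"
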
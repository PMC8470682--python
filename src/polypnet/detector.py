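"""Anchor-grid single-stage polyp detector.

The network takes a 128x128 frame (1 grayscale or 3 color channels)
through three multi-kernel convolution blocks with 2x2/2 max pooling
(128 -> 64 -> 32 -> 16), three further multi-kernel blocks at 16x16, and a
1x1 convolution head emitting 24 channels per cell — interpreted as 8
anchors x (objectness, x-offset, y-offset).  The eight anchor box shapes,
in original-frame pixels, are fixed priors; a detection inherits its
anchor's width and height, while its center is the cell origin plus the
sigmoid-squashed offsets.  Cell coordinates map back to the original frame
by (image_w/16, image_h/16), since anchors as large as 216 px refer to the
native 640x480 frame rather than the 128x128 network input.  The default
emission cutoff on objectness is 0.2.

Training targets (the reference system does not publish its scheme) follow
the usual grid-detector convention: each ground-truth box activates the
single best-IoU anchor in the cell containing its center; the loss is
weighted binary cross-entropy on objectness plus squared error on the
sigmoid offsets at positive entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import BBox, rgb_to_grayscale, resize_image
from .nn import (
    Adam,
    BatchNorm2D,
    MaxPool2D,
    MultiKernelConv2D,
    PointwiseConv2D,
    ReLU,
    Sequential,
)
from .nn.ops import sigmoid

#: the eight anchor (width, height) priors, original-frame pixels
ANCHORS: tuple[tuple[int, int], ...] = (
    (16, 16),
    (32, 32),
    (24, 48),
    (48, 24),
    (60, 80),
    (108, 72),
    (216, 144),
    (180, 180),
)

GRID_SIZE = 16
N_ANCHORS = len(ANCHORS)
INPUT_SIZE = 128
DETECTION_CUTOFF = 0.2


@dataclass(frozen=True)
class Detection:
    """One decoded box with its objectness score."""

    box: BBox
    score: float


@dataclass
class DetectorConfig:
    """Training recipe (none of this is published; all of it is tunable)."""

    in_channels: int = 1
    epochs: int = 10
    batch_size: int = 16
    lr: float = 1e-3
    pos_weight: float = 5.0
    off_weight: float = 1.0
    cutoff: float = DETECTION_CUTOFF
    combine: str = "sum"
    grayscale_mode: str = "standard"


def build_detector(in_channels: int, seed: int = 0, combine: str = "sum") -> Sequential:
    """Assemble the detection network; audit via ``model.shape_trace``."""
    if in_channels not in (1, 3):
        raise ValueError("in_channels must be 1 (grayscale) or 3 (color)")
    rng = np.random.default_rng(seed)
    layers: list = []

    def block(idx: int, cin: int, cout: int, pool: bool) -> int:
        layers.append((f"conv{idx}", MultiKernelConv2D(cin, cout, rng, combine=combine)))
        layers.append((f"bn{idx}", BatchNorm2D(cout)))
        layers.append((f"relu{idx}", ReLU()))
        if pool:
            layers.append((f"pool{idx}", MaxPool2D(2, 2)))
        return cout

    c = in_channels
    c = block(1, c, 16, pool=True)
    c = block(2, c, 32, pool=True)
    c = block(3, c, 64, pool=True)
    c = block(4, c, 128, pool=False)
    c = block(5, c, 128, pool=False)
    c = block(6, c, 128, pool=False)
    head = PointwiseConv2D(c, N_ANCHORS * 3, rng)
    # start objectness strongly negative so an untrained net emits nothing
    # at the 0.2 cutoff; training raises scores only where lesions appear
    head.params["b"][0::3] = -2.0
    layers.append(("head", head))
    return Sequential(layers)


def _split_grid(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(16,16,24) raw head output -> (obj, tx, ty) each (16,16,8)."""
    if grid.shape != (GRID_SIZE, GRID_SIZE, N_ANCHORS * 3):
        raise ValueError(f"expected {GRID_SIZE}x{GRID_SIZE}x{N_ANCHORS * 3} grid, got {grid.shape}")
    g = grid.reshape(GRID_SIZE, GRID_SIZE, N_ANCHORS, 3)
    return g[..., 0], g[..., 1], g[..., 2]


def decode_detections(
    grid: np.ndarray,
    anchors: tuple[tuple[int, int], ...] = ANCHORS,
    cutoff: float = DETECTION_CUTOFF,
    image_w: int = 640,
    image_h: int = 480,
    suppress: bool = True,
    iou_threshold: float = 0.5,
) -> list[Detection]:
    """Decode a raw 16x16x24 head output into scored, clipped boxes.

    For every cell (r, c) and anchor k with sigmoid(objectness) >= cutoff:
    center = ((c + sig(tx)) * image_w/16, (r + sig(ty)) * image_h/16), box
    dims = anchor k's (w, h), clipped to the frame.  Detections come back
    sorted by descending score, after optional greedy IoU-0.5 suppression.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    obj, tx, ty = _split_grid(np.asarray(grid, dtype=np.float64))
    scores = sigmoid(obj)
    sx, sy = sigmoid(tx), sigmoid(ty)
    cell_w, cell_h = image_w / GRID_SIZE, image_h / GRID_SIZE
    cand: list[Detection] = []
    rr, cc, kk = np.nonzero(scores >= cutoff)
    for r, c, k in zip(rr, cc, kk):
        aw, ah = anchors[k]
        cx = (c + sx[r, c, k]) * cell_w
        cy = (r + sy[r, c, k]) * cell_h
        x0 = int(round(cx - aw / 2.0))
        y0 = int(round(cy - ah / 2.0))
        x0c, y0c = max(0, x0), max(0, y0)
        x1c, y1c = min(image_w, x0 + aw), min(image_h, y0 + ah)
        if x1c - x0c < 1 or y1c - y0c < 1:
            continue
        cand.append(Detection(BBox(x0c, y0c, x1c - x0c, y1c - y0c), float(scores[r, c, k])))
    cand.sort(key=lambda d: -d.score)
    if not suppress:
        return cand
    kept: list[Detection] = []
    for det in cand:
        if all(det.box.iou(k.box) < iou_threshold for k in kept):
            kept.append(det)
    return kept


@dataclass
class TargetGrid:
    """Training targets: objectness in {0,1} and offset pair per anchor."""

    obj: np.ndarray  # (16,16,8) float32
    offsets: np.ndarray  # (16,16,8,2) float32, valid where obj == 1
    n_pos: int = 0

    @classmethod
    def empty(cls) -> "TargetGrid":
        return cls(
            obj=np.zeros((GRID_SIZE, GRID_SIZE, N_ANCHORS), np.float32),
            offsets=np.zeros((GRID_SIZE, GRID_SIZE, N_ANCHORS, 2), np.float32),
        )


def _anchor_iou(gt: BBox, anchor: tuple[int, int]) -> float:
    """IoU of the GT box with an anchor-shaped box sharing its center."""
    iw = min(gt.width, anchor[0])
    ih = min(gt.height, anchor[1])
    inter = iw * ih
    union = gt.area + anchor[0] * anchor[1] - inter
    return inter / union


def assign_targets(
    gt_boxes: list[BBox],
    image_w: int,
    image_h: int,
    anchors: tuple[tuple[int, int], ...] = ANCHORS,
) -> TargetGrid:
    """Build the positive/negative target grid for one image.

    The cell containing each GT center goes positive for the single
    highest-IoU anchor (ties break to the lowest anchor index); offset
    targets are the center's fractional position within its cell.
    """
    tg = TargetGrid.empty()
    cell_w, cell_h = image_w / GRID_SIZE, image_h / GRID_SIZE
    for gt in gt_boxes:
        cx, cy = gt.center
        if not (0 <= cx <= image_w and 0 <= cy <= image_h):
            raise ValueError(f"GT center ({cx}, {cy}) outside {image_w}x{image_h} image")
        c = min(int(cx / cell_w), GRID_SIZE - 1)
        r = min(int(cy / cell_h), GRID_SIZE - 1)
        ious = [_anchor_iou(gt, a) for a in anchors]
        k = int(np.argmax(ious))  # argmax takes the first (lowest) index on ties
        tg.obj[r, c, k] = 1.0
        tg.offsets[r, c, k, 0] = cx / cell_w - c
        tg.offsets[r, c, k, 1] = cy / cell_h - r
        tg.n_pos += 1
    return tg


def detection_loss(
    logits: np.ndarray,
    targets: list[TargetGrid],
    pos_weight: float = 5.0,
    off_weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Objectness BCE + offset squared error; returns (loss, dL/dlogits).

    ``logits`` is the raw head output (n, 16, 16, 24).  Positive and
    negative objectness entries are averaged separately and combined with
    weight ``pos_weight`` on the positive mean — a lone positive among
    2047 negative anchors per frame must not drown — and the offset term
    averages the squared error of the sigmoid offsets over positives
    only.  The loss is exactly zero when the activations equal the
    targets everywhere they are scored.
    """
    n = logits.shape[0]
    if len(targets) != n:
        raise ValueError("batch size mismatch between logits and targets")
    g = logits.reshape(n, GRID_SIZE, GRID_SIZE, N_ANCHORS, 3).astype(np.float64)
    t_obj = np.stack([t.obj for t in targets]).astype(np.float64)
    t_off = np.stack([t.offsets for t in targets]).astype(np.float64)
    pos = t_obj == 1.0
    n_cells = n * GRID_SIZE * GRID_SIZE * N_ANCHORS
    n_pos = max(1, int(pos.sum()))
    n_neg = max(1, n_cells - int(pos.sum()))

    s = sigmoid(g[..., 0])
    # xlogy-style terms so exact matches (s == t in {0,1}) contribute 0;
    # fully mismatched saturated entries are clamped to a large finite
    # penalty instead of inf (their gradient s - t is finite anyway)
    tiny = 1e-12
    lp = np.where(t_obj > 0, np.log(np.maximum(s, tiny)), 0.0)
    ln = np.where(t_obj < 1, np.log(np.maximum(1.0 - s, tiny)), 0.0)
    loss_obj = float(-pos_weight * lp.sum() / n_pos - ln.sum() / n_neg)

    soff = sigmoid(g[..., 1:3])
    err = np.where(pos[..., None], soff - t_off, 0.0)
    loss_off = float(off_weight * (err**2).sum() / n_pos)

    grad = np.zeros_like(g)
    grad[..., 0] = np.where(
        pos, pos_weight * (s - t_obj) / n_pos, (s - t_obj) / n_neg
    )
    grad[..., 1:3] = off_weight * 2.0 * err * soff * (1.0 - soff) / n_pos
    return loss_obj + loss_off, grad.reshape(logits.shape).astype(np.float32)


def prepare_image(
    img: np.ndarray,
    in_channels: int,
    size_hw: tuple[int, int],
    grayscale_mode: str = "standard",
) -> np.ndarray:
    """Channel-adapt, resize and scale a frame to a float32 network input."""
    if in_channels == 1 and img.ndim == 3 and img.shape[2] == 3:
        img = rgb_to_grayscale(img, mode=grayscale_mode)
    elif in_channels == 3 and img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    img = resize_image(img, size_hw[0], size_hw[1])
    if img.ndim == 2:
        img = img[..., None]
    return img.astype(np.float32) / 255.0


def train_detector(
    dataset: list[tuple[np.ndarray, list[BBox]]],
    config: DetectorConfig,
    seed: int,
) -> tuple[Sequential, str]:
    """Train on (frame, GT boxes) pairs; returns (model, text training log).

    Fully reproducible: the same dataset, config and seed yield an
    identical model and a byte-identical log.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    model = build_detector(config.in_channels, seed=int(rng.integers(2**31)), combine=config.combine)
    opt = Adam(model, lr=config.lr)

    xs = np.stack(
        [
            prepare_image(img, config.in_channels, (INPUT_SIZE, INPUT_SIZE), config.grayscale_mode)
            for img, _ in dataset
        ]
    )
    targets = [assign_targets(boxes, img.shape[1], img.shape[0]) for img, boxes in dataset]

    lines = [f"n={len(dataset)} epochs={config.epochs} batch={config.batch_size} lr={config.lr}"]
    n = len(dataset)
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = model.forward(xs[idx], training=True)
            loss, grad = detection_loss(
                logits, [targets[i] for i in idx], config.pos_weight, config.off_weight
            )
            model.backward(grad)
            opt.step()
            losses.append(loss)
        lines.append(f"epoch={epoch} loss={np.mean(losses):.6f}")
    recalibrate_batchnorm(model, xs, config.batch_size)
    return model, "\n".join(lines) + "\n"


def recalibrate_batchnorm(model: Sequential, xs: np.ndarray, batch_size: int) -> None:
    """One forward sweep in training mode to settle BN running statistics.

    After short training runs the exponential running averages still lag
    the population statistics, which shifts inference-time activations;
    a final statistics-only pass fixes the operating point.
    """
    for start in range(0, len(xs), batch_size):
        model.forward(xs[start : start + batch_size], training=True)


def detect(
    image: np.ndarray,
    model: Sequential,
    cutoff: float = DETECTION_CUTOFF,
    grayscale_mode: str = "standard",
    suppress: bool = True,
) -> list[Detection]:
    """Resize -> forward -> decode; boxes come back in original coordinates."""
    in_channels = model.layers[0][1].cin
    h, w = image.shape[:2]
    x = prepare_image(image, in_channels, (INPUT_SIZE, INPUT_SIZE), grayscale_mode)
    grid = model.forward(x[None], training=False)[0]
    return decode_detections(grid, cutoff=cutoff, image_w=w, image_h=h, suppress=suppress)


def save_weights(model: Sequential, path: str | Path, input_shape: tuple) -> None:
    """Native .npz checkpoint plus a portable text layer manifest."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    manifest_path = path.with_suffix(".manifest.txt")
    manifest_path.write_text(model.manifest(input_shape))


def load_weights(model: Sequential, path: str | Path) -> Sequential:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path) as data:
        model.load_state_dict(dict(data))
    return model
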
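"""Image and annotation I/O for colonoscopy stills.

Rasters are numpy uint8 arrays, HxW (grayscale) or HxWx3 (RGB), values
0-255.  Boxes use a 0-based, top-left-origin, half-open pixel convention:
a box covers columns x_min <= x < x_min + width and rows
y_min <= y < y_min + height.

Ground truth arrives either as bounding-box rows in a tab-separated
annotation table (schema below) or as a binary lesion mask alongside the
frame, from which tight boxes are extracted per connected component.

Annotation schema (TSV, one row per box; a row with empty box fields
registers a polyp-free frame)::

    image_path  image_w  image_h  x_min  y_min  width  height  class_label  modality

``class_label`` is empty, ``neoplastic`` or ``hyperplastic``; ``modality``
is one of WL, NBI, synthetic-WL, synthetic-NBI.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage import measure, transform

#: Luma weights. "standard" is ITU-R BT.601; "legacy" is a variant with
#: weights (0.229, 0.587, 0.117) that circulates in some published
#: detection systems (an apparent transcription of BT.601 that does not
#: sum to 1); it is kept selectable for fidelity with models trained
#: under it.
GRAYSCALE_COEFFICIENTS: dict[str, tuple[float, float, float]] = {
    "standard": (0.299, 0.587, 0.114),
    "legacy": (0.229, 0.587, 0.117),
}

CLASS_LABELS = ("neoplastic", "hyperplastic")
MODALITIES = ("WL", "NBI", "synthetic-WL", "synthetic-NBI")


@dataclass(frozen=True)
class BBox:
    """Axis-aligned pixel box, half-open, 0-based, y down."""

    x_min: int
    y_min: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"degenerate box {self.width}x{self.height}")

    @property
    def x_max(self) -> int:  # exclusive
        return self.x_min + self.width

    @property
    def y_max(self) -> int:  # exclusive
        return self.y_min + self.height

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) in continuous pixel coordinates."""
        return (self.x_min + self.width / 2.0, self.y_min + self.height / 2.0)

    def contains_point(self, x: float, y: float) -> bool:
        """Edge-inclusive point-in-box test (both borders count as inside)."""
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def iou(self, other: "BBox") -> float:
        ix = max(0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union else 0.0

    def inside(self, width: int, height: int) -> bool:
        return 0 <= self.x_min and 0 <= self.y_min and self.x_max <= width and self.y_max <= height


@dataclass
class AnnotatedImage:
    """One frame plus its ground truth."""

    image_path: str
    image_w: int
    image_h: int
    gt_boxes: list[BBox] = field(default_factory=list)
    class_label: str | None = None
    modality: str = "WL"

    def __post_init__(self) -> None:
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        for box in self.gt_boxes:
            if not box.inside(self.image_w, self.image_h):
                raise ValueError(
                    f"box {box} outside {self.image_w}x{self.image_h} image {self.image_path}"
                )


def _check_raster(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (1, 3):
        return img
    raise ValueError(f"expected HxW or HxWx{{1,3}} raster, got shape {img.shape}")


def rgb_to_grayscale(
    img: np.ndarray,
    coefficients: tuple[float, float, float] | None = None,
    mode: str = "standard",
) -> np.ndarray:
    """Weighted luma conversion, rounded half-away-from-zero to uint8.

    ``coefficients`` overrides the named ``mode`` (see
    :data:`GRAYSCALE_COEFFICIENTS`).  Gray = cR*R + cG*G + cB*B per pixel,
    then round and clip to 0..255.
    """
    img = _check_raster(img)
    if img.ndim == 2 or img.shape[2] == 1:
        raise ValueError("already grayscale")
    if coefficients is None:
        coefficients = GRAYSCALE_COEFFICIENTS[mode]
    c = np.asarray(coefficients, dtype=np.float64)
    if c.shape != (3,):
        raise ValueError("coefficients must be a triple")
    if (c < 0).any():
        raise ValueError("coefficients must be non-negative")
    gray = img.astype(np.float64) @ c
    # round half away from zero (values are non-negative here)
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)


def mask_to_bboxes(mask: np.ndarray) -> list[BBox]:
    """Tight boxes of the 8-connected foreground components of a binary mask.

    The box spans the min/max row and column of each component — the
    standard conversion of a clinician-drawn lesion mask to box ground
    truth.  An all-zero mask yields an empty list (a negative frame).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    labels = measure.label(mask, connectivity=2)
    boxes = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox  # half-open
        boxes.append(BBox(x_min=int(c0), y_min=int(r0), width=int(c1 - c0), height=int(r1 - r0)))
    boxes.sort(key=lambda b: (b.y_min, b.x_min))
    return boxes


def resize_image(img: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Bilinear resize to exactly (target_h, target_w), uint8 output."""
    img = _check_raster(img)
    if target_h < 1 or target_w < 1:
        raise ValueError("target dims must be positive")
    if img.shape[0] == target_h and img.shape[1] == target_w:
        return img.copy()
    out = transform.resize(
        img.astype(np.float64),
        (target_h, target_w) + img.shape[2:],
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    """Read a TIFF (native format here) or other raster file as uint8."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = np.asarray(Image.open(path))
    return _check_raster(np.asarray(img, dtype=np.uint8))


def save_image(img: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    img = _check_raster(np.ascontiguousarray(img, dtype=np.uint8))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        Image.fromarray(img).save(path)


_ANNOTATION_HEADER = [
    "image_path",
    "image_w",
    "image_h",
    "x_min",
    "y_min",
    "width",
    "height",
    "class_label",
    "modality",
]


def write_annotations(records: list[AnnotatedImage], path: str | Path) -> None:
    """Write records to the TSV annotation schema (one row per box)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_HEADER)
        for rec in records:
            base = [rec.image_path, rec.image_w, rec.image_h]
            tail = [rec.class_label or "", rec.modality]
            if rec.gt_boxes:
                for box in rec.gt_boxes:
                    writer.writerow(base + [box.x_min, box.y_min, box.width, box.height] + tail)
            else:
                writer.writerow(base + ["", "", "", ""] + tail)


def read_annotations(path: str | Path) -> list[AnnotatedImage]:
    """Read the TSV annotation schema back into records.

    Rows sharing an image_path are merged (in file order) into one record.
    Malformed rows are rejected with their 1-based row number.
    """
    records: dict[str, AnnotatedImage] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _ANNOTATION_HEADER:
            raise ValueError(f"bad annotation header: {header}")
        for i, row in enumerate(reader, start=2):
            if len(row) != len(_ANNOTATION_HEADER):
                raise ValueError(f"row {i}: expected {len(_ANNOTATION_HEADER)} fields, got {len(row)}")
            (img_path, w_s, h_s, x_s, y_s, bw_s, bh_s, label, modality) = row
            try:
                img_w, img_h = int(w_s), int(h_s)
            except ValueError as exc:
                raise ValueError(f"row {i}: bad image dims {w_s!r}x{h_s!r}") from exc
            box_fields = (x_s, y_s, bw_s, bh_s)
            if any(box_fields) != all(box_fields):
                raise ValueError(f"row {i}: incomplete box fields {box_fields}")
            box = None
            if all(box_fields):
                try:
                    box = BBox(int(x_s), int(y_s), int(bw_s), int(bh_s))
                except ValueError as exc:
                    raise ValueError(f"row {i}: {exc}") from exc
                if not box.inside(img_w, img_h):
                    raise ValueError(f"row {i}: box outside {img_w}x{img_h} image")
            rec = records.get(img_path)
            if rec is None:
                try:
                    rec = AnnotatedImage(
                        image_path=img_path,
                        image_w=img_w,
                        image_h=img_h,
                        class_label=label or None,
                        modality=modality,
                    )
                except ValueError as exc:
                    raise ValueError(f"row {i}: {exc}") from exc
                records[img_path] = rec
            if box is not None:
                rec.gt_boxes.append(box)
    return list(records.values())
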
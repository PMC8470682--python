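"""Seed-deterministic synthetic colonoscopy scenes with box/label ground truth.

The generator emulates the image regime of endoscopic stills just closely
enough to exercise a detection/classification pipeline end to end: a
640x480 frame with a dark lumen, radial mucosal wrinkle ridges, specular
highlights and sensor noise, in either a white-light-like (pinkish) or
narrow-band-like (red-suppressed, green/blue-boosted) palette.  Polyps are
shaded elliptical protrusions carrying one of two surface textures that
mirror the optical classes used clinically: "neoplastic" lesions get dark
tubular/branched vessel strokes, "hyperplastic" lesions get light dots of
uniform size.  Target box areas are controllable so datasets can straddle
the 1600- and 1800-pixel analysis thresholds.

No attempt is made at optical realism (hemoglobin spectra, lens
distortion); the point is a learnable, fully reproducible stand-in for
hospital data.  Identical spec + seed yields bit-identical frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import AnnotatedImage, BBox, save_image, write_annotations

PALETTES = {
    # per-channel gain applied to the scalar luminance field
    "WL": (1.00, 0.62, 0.52),
    "NBI": (0.35, 0.95, 0.78),
}

#: background luminance is capped below saturation so that compositing a
#: polyp always changes the underlying pixels (specular pixels excepted)
_LUM_CAP = 0.92


@dataclass(frozen=True)
class PolypSpec:
    """One elliptical lesion: geometry, size target and surface texture."""

    center: tuple[float, float]  # (cx, cy) pixels
    target_area: float  # tight-box area, px
    texture_class: str  # "neoplastic" | "hyperplastic"
    axis_ratio: float = 1.0  # semi-major / semi-minor before rotation
    rotation: float = 0.0  # degrees
    contrast: float = 0.6  # 0..1 protrusion strength

    def __post_init__(self) -> None:
        if self.texture_class not in ("neoplastic", "hyperplastic"):
            raise ValueError(f"unknown texture class {self.texture_class!r}")
        if self.target_area < 25:
            raise ValueError("target_area too small to render")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")

    def semi_axes(self) -> tuple[float, float]:
        """Semi-axes (a, b) such that the rotated ellipse's tight pixel box
        has area ~= target_area (pixel sampling adds ~1 px per dimension,
        which the quadratic correction below accounts for)."""
        th = math.radians(self.rotation)
        a0, b0 = self.axis_ratio, 1.0
        ex0 = math.hypot(a0 * math.cos(th), b0 * math.sin(th))
        ey0 = math.hypot(a0 * math.sin(th), b0 * math.cos(th))
        rho = ex0 / ey0
        # solve (2*rho*t + 1)(2*t + 1) = target_area for t = ey
        A = float(self.target_area)
        t = (-2 * (rho + 1) + math.sqrt(4 * (rho + 1) ** 2 + 16 * rho * (A - 1))) / (8 * rho)
        s = t / ey0
        return a0 * s, b0 * s

    def tight_extents(self) -> tuple[float, float]:
        """Half-extents (ex, ey) of the rotated ellipse's bounding box."""
        a, b = self.semi_axes()
        th = math.radians(self.rotation)
        return (
            math.hypot(a * math.cos(th), b * math.sin(th)),
            math.hypot(a * math.sin(th), b * math.cos(th)),
        )


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one synthetic frame."""

    width: int = 640
    height: int = 480
    palette: str = "WL"
    vignette_strength: float = 0.55
    wrinkle_frequency: float = 7.0
    wrinkle_amplitude: float = 0.10
    specular_count: int = 8
    noise_level: float = 0.015
    polyps: tuple[PolypSpec, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("frame dims must be >= 64")
        if self.palette not in PALETTES:
            raise ValueError(f"palette must be one of {sorted(PALETTES)}")
        if len(self.polyps) > 4:
            raise ValueError("at most 4 polyps per frame")


def generate_background(spec: SceneSpec) -> np.ndarray:
    """Render the polyp-free frame for ``spec`` (uint8 HxWx3)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # lumen (dark hole) somewhere off-center
    lx = w * (0.5 + rng.uniform(-0.18, 0.18))
    ly = h * (0.5 + rng.uniform(-0.18, 0.18))
    diag = math.hypot(w, h) / 2.0
    d = np.hypot(xx - lx, yy - ly) / diag

    lum = np.full((h, w), 0.66)
    # lumen darkening and corner falloff both scale with vignette_strength,
    # so a zero-strength spec leaves the depth shading off entirely
    lum -= spec.vignette_strength * 0.73 * np.exp(-((d / 0.22) ** 2))
    lum -= spec.vignette_strength * 0.45 * d**2

    # wrinkle ridges: angular sinusoid around the lumen, bent by smooth noise
    theta = np.arctan2(yy - ly, xx - lx)
    bend = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=30.0)
    ridges = np.sin(spec.wrinkle_frequency * theta + rng.uniform(0, 2 * math.pi) + 2.5 * bend)
    lum += spec.wrinkle_amplitude * ridges * np.clip(d, 0.15, 1.0)

    # smoothed mottle so the wall is not analytically flat; scales with the
    # wrinkle amplitude (it is wall texture, like the ridges)
    lum += 0.5 * spec.wrinkle_amplitude * ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=12.0
    )
    lum = np.clip(lum, 0.05, _LUM_CAP)

    # specular highlights: small saturated discs
    for _ in range(spec.specular_count):
        sx, sy = rng.uniform(0, w), rng.uniform(0, h)
        sig = rng.uniform(1.5, 4.0)
        spot = np.exp(-(((xx - sx) ** 2 + (yy - sy) ** 2) / (2 * sig**2)))
        lum = np.maximum(lum, 0.98 * spot)

    if spec.noise_level > 0:
        lum = lum + rng.normal(0.0, spec.noise_level, size=(h, w))
    lum = np.clip(lum, 0.0, 1.0)

    gains = PALETTES[spec.palette]
    img = np.stack([lum * g for g in gains], axis=-1)
    return np.clip(np.floor(img * 255.0 + 0.5), 0, 255).astype(np.uint8)


def _stroke_mask(rng: np.random.Generator, inside: np.ndarray, box: tuple) -> np.ndarray:
    """Dark-vessel texture: branched random-walk strokes within the lesion."""
    y0, y1, x0, x1 = box
    hh, ww = y1 - y0, x1 - x0
    mask = np.zeros((hh, ww), dtype=bool)
    # sparse coverage (~10-20% of the lesion): vessels must stay the dark
    # minority against the mucosal surface, or the texture reads as its
    # negative (light gaps on a dark ground)
    area = int(inside.sum())
    n_strokes = max(3, area // 900)
    todo = []
    for _ in range(n_strokes):
        ys, xs = np.nonzero(inside)
        if len(ys) == 0:
            return mask
        j = rng.integers(len(ys))
        todo.append((float(xs[j]), float(ys[j]), rng.uniform(0, 2 * math.pi), int(0.6 * math.sqrt(area))))
    while todo:
        x, y, heading, steps = todo.pop()
        for _ in range(steps):
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= yi < hh and 0 <= xi < ww) or not inside[yi, xi]:
                break
            mask[yi, xi] = True
            heading += rng.normal(0.0, 0.35)
            x += 1.3 * math.cos(heading)
            y += 1.3 * math.sin(heading)
            if rng.random() < 0.03 and len(todo) < 40:
                todo.append((x, y, heading + rng.choice((-1, 1)) * rng.uniform(0.7, 1.3), steps // 2))
    return ndimage.binary_dilation(mask, structure=np.ones((2, 2), bool)) & inside


def _dot_mask(rng: np.random.Generator, inside: np.ndarray) -> np.ndarray:
    """Light-dot texture: jittered grid of uniform small spots."""
    hh, ww = inside.shape
    mask = np.zeros((hh, ww), dtype=bool)
    spacing = 5
    for gy in range(0, hh, spacing):
        for gx in range(0, ww, spacing):
            x = gx + rng.uniform(-1.2, 1.2)
            y = gy + rng.uniform(-1.2, 1.2)
            xi, yi = int(round(x)), int(round(y))
            for dy, dx in ((0, 0), (0, 1), (1, 0), (0, -1), (-1, 0)):
                yj, xj = yi + dy, xi + dx
                if 0 <= yj < hh and 0 <= xj < ww and inside[yj, xj]:
                    mask[yj, xj] = True
    return mask


def render_polyp(
    frame: np.ndarray, polyp: PolypSpec, seed: int
) -> tuple[np.ndarray, BBox, str]:
    """Composite one lesion onto ``frame``.

    Returns (new frame, tight box of the composited pixels, class label).
    The polyp must lie fully inside the frame and must actually change
    pixels (zero contrast is rejected as a degenerate lesion).
    """
    h, w = frame.shape[:2]
    cx, cy = polyp.center
    ex, ey = polyp.tight_extents()
    if cx - ex < 0 or cy - ey < 0 or cx + ex > w - 1 or cy + ey > h - 1:
        raise ValueError(f"polyp box exceeds frame bounds ({cx:.0f},{cy:.0f}) ±({ex:.0f},{ey:.0f})")
    if polyp.contrast == 0.0:
        raise ValueError("degenerate polyp: zero contrast renders no pixels")

    rng = np.random.default_rng(seed)
    a, b = polyp.semi_axes()
    th = math.radians(polyp.rotation)
    x0, x1 = int(math.floor(cx - ex)), int(math.ceil(cx + ex)) + 1
    y0, y1 = int(math.floor(cy - ey)), int(math.ceil(cy + ey)) + 1
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    xr = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
    yr = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
    e = (xr / a) ** 2 + (yr / b) ** 2
    inside = e <= 1.0
    dome = np.sqrt(np.clip(1.0 - e, 0.0, None))

    # strictly positive brightness bump everywhere inside the ellipse, so
    # the composited-pixel mask is exactly the filled ellipse
    bump = polyp.contrast * (0.10 + 0.40 * dome)
    if polyp.texture_class == "neoplastic":
        texture = _stroke_mask(rng, inside, (y0, y1, x0, x1))
        bump = np.where(texture, bump * 0.22, bump)  # dark vessels
    else:
        texture = _dot_mask(rng, inside)
        bump = np.where(texture, np.minimum(bump * 2.1, 0.9), bump)  # light dots
    bump = np.where(inside, bump, 0.0)

    out = frame.copy()
    patch = out[y0:y1, x0:x1].astype(np.float64) / 255.0
    # lesion tissue occludes the wall behind it: flatten background detail
    # (wrinkles, speculars) under the ellipse before shading the dome
    smooth = np.stack(
        [ndimage.gaussian_filter(patch[..., ch], 3.0) for ch in range(patch.shape[-1])],
        axis=-1,
    )
    patch = np.where(inside[..., None], smooth, patch)
    patch += bump[..., None]
    out[y0:y1, x0:x1] = np.clip(np.floor(patch * 255.0 + 0.5), 0, 255).astype(np.uint8)

    changed = (out[y0:y1, x0:x1] != frame[y0:y1, x0:x1]).any(axis=-1)
    if not changed.any():
        raise ValueError("degenerate polyp: compositing changed no pixels")
    rows = np.nonzero(changed.any(axis=1))[0]
    cols = np.nonzero(changed.any(axis=0))[0]
    box = BBox(
        x_min=int(x0 + cols[0]),
        y_min=int(y0 + rows[0]),
        width=int(cols[-1] - cols[0] + 1),
        height=int(rows[-1] - rows[0] + 1),
    )
    return out, box, polyp.texture_class


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, list[tuple[BBox, str]]]:
    """Background plus all polyps of ``spec``; deterministic in spec.seed."""
    frame = generate_background(spec)
    annotations = []
    for i, polyp in enumerate(spec.polyps):
        frame, box, label = render_polyp(frame, polyp, seed=spec.seed * 1000003 + i + 1)
        annotations.append((box, label))
    return frame, annotations


def sample_polyp(
    rng: np.random.Generator,
    width: int,
    height: int,
    area_range: tuple[float, float],
    texture_class: str,
) -> PolypSpec:
    """Draw one random lesion spec that fits the frame with margin."""
    lo, hi = area_range
    area = float(rng.uniform(lo, hi))
    ratio = float(rng.uniform(0.7, 1.5))
    rotation = float(rng.uniform(0.0, 180.0))
    contrast = float(rng.uniform(0.45, 0.8))
    probe = PolypSpec((0.0, 0.0), area, texture_class, ratio, rotation, contrast)
    ex, ey = probe.tight_extents()
    margin = 4.0
    cx = float(rng.uniform(ex + margin, width - 1 - ex - margin))
    cy = float(rng.uniform(ey + margin, height - 1 - ey - margin))
    return replace(probe, center=(cx, cy))


@dataclass
class DatasetBundle:
    """In-memory synthetic dataset plus its manifest (and files, if written)."""

    records: list[AnnotatedImage]
    images: list[np.ndarray]
    manifest: pd.DataFrame
    out_dir: Path | None = None


def generate_dataset(
    n_images: int,
    seed: int,
    out_dir: str | Path | None = None,
    class_mix: float = 0.5,
    negatives_fraction: float = 0.5,
    palette_mix: float = 0.5,
    area_range: tuple[float, float] = (800.0, 6400.0),
    n_polyps_range: tuple[int, int] = (1, 1),
    width: int = 640,
    height: int = 480,
) -> DatasetBundle:
    """Generate ``n_images`` frames with ground truth, fully seed-determined.

    ``class_mix`` is the neoplastic fraction among polyp frames (0.5
    mirrors the balanced training design), ``negatives_fraction`` the
    share of polyp-free frames (0.5 mirrors a 900-polyp/900-normal test
    design), ``palette_mix`` the share of NBI-like frames.  ``area_range``
    bounds the per-lesion tight-box pixel area; the default straddles the
    1600 and 1800 px analysis thresholds.  When ``out_dir`` is given,
    frames are written as TIFF next to ``annotations.tsv`` and
    ``manifest.tsv``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    records: list[AnnotatedImage] = []
    images: list[np.ndarray] = []
    rows = []
    for i in range(n_images):
        negative = rng.random() < negatives_fraction
        palette = "NBI" if rng.random() < palette_mix else "WL"
        scene_seed = int(rng.integers(0, 2**31 - 1))
        polyps: tuple[PolypSpec, ...] = ()
        label: str | None = None
        if not negative:
            label = "neoplastic" if rng.random() < class_mix else "hyperplastic"
            n_polyps = int(rng.integers(n_polyps_range[0], n_polyps_range[1] + 1))
            polyps = tuple(
                sample_polyp(rng, width, height, area_range, label) for _ in range(n_polyps)
            )
        spec = SceneSpec(width=width, height=height, palette=palette, polyps=polyps, seed=scene_seed)
        frame, annotations = generate_scene(spec)
        name = f"frame_{i:05d}.tif"
        rec = AnnotatedImage(
            image_path=name,
            image_w=width,
            image_h=height,
            gt_boxes=[box for box, _ in annotations],
            class_label=label,
            modality=f"synthetic-{palette}",
        )
        records.append(rec)
        images.append(frame)
        for box, _ in annotations:
            rows.append(
                dict(
                    image_path=name,
                    palette=palette,
                    class_label=label or "",
                    x_min=box.x_min,
                    y_min=box.y_min,
                    width=box.width,
                    height=box.height,
                    area=box.area,
                    scene_seed=scene_seed,
                )
            )
        if not annotations:
            rows.append(
                dict(
                    image_path=name,
                    palette=palette,
                    class_label="",
                    x_min=-1,
                    y_min=-1,
                    width=0,
                    height=0,
                    area=0,
                    scene_seed=scene_seed,
                )
            )
        if out_path is not None:
            save_image(frame, out_path / name)

    manifest = pd.DataFrame(rows)
    if out_path is not None:
        write_annotations(records, out_path / "annotations.tsv")
        manifest.to_csv(out_path / "manifest.tsv", sep="\t", index=False)
    return DatasetBundle(records=records, images=images, manifest=manifest, out_dir=out_path)
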
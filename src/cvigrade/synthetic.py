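"""Synthetic leg-image generator with exact patch-level ground truth.

Generates 250 x 700 photographs of a stylized lower limb: a tapered
silhouette of skin-toned texture on a plain background, with lesion
textures painted per severity class —

* mild: optionally a few thin dark curvilinear strokes (concept 2,
  reticular veins / telangiectasia); some mild legs carry no lesion;
* moderate: thick tortuous dark ridges (concept 3, varicose veins);
* severe: dark diffuse patches (concept 4, pigmentation/edema) and/or
  bright irregular blobs (concept 5, ulcers), biased toward the lower
  half of the leg (ankle region) by a location prior.

Painted pixels are recorded in a per-pixel concept canvas from which the
ground-truth label of every grid patch is derived as the plurality
concept among its painted pixels (ties toward the lower concept number);
a patch without painted pixels is normal skin. The scene label is
recoverable from the painted concepts by construction. Everything is
deterministic under a seeded generator.

Texture realism is not a goal: contrasts are set so that the concepts
are clearly separable, which is the regime in which the end-to-end
pipeline is exercised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import DEFAULT_SCALES, GridSpec, divide
from .image import (CANONICAL_HEIGHT, CANONICAL_WIDTH, LegImage,
                    ValidationError, save_image)

H, W = CANONICAL_HEIGHT, CANONICAL_WIDTH

SKIN_RGB = (205.0, 160.0, 130.0)
BACKGROUND_RGB = (70.0, 70.0, 72.0)

#: painted color per concept (RGB)
CONCEPT_RGB = {
    2: (110.0, 45.0, 55.0),    # thin reddish reticular veins
    3: (70.0, 55.0, 100.0),    # thick dark bluish varicose ridges
    4: (115.0, 75.0, 55.0),    # brownish diffuse pigmentation/edema
    5: (245.0, 225.0, 185.0),  # bright irregular ulcer blobs
}


@dataclass
class SynthSpec:
    """Generation parameters of the synthetic study conditions."""

    n_per_class: int = 30
    seed: int = 0
    #: probability that a mild leg carries reticular-vein strokes at all
    mild_stroke_prob: float = 0.7
    #: probability that severe lesions (concepts 4/5) sit in the lower half
    lower_half_prior: float = 0.9
    #: additive Gaussian noise on the skin texture (intensity units)
    skin_noise_sd: float = 5.0
    #: stroke widths (px) for thin (concept 2) and thick (concept 3) vessels
    thin_width: tuple[int, int] = (1, 2)
    thick_width: tuple[int, int] = (6, 11)

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        for p in (self.mild_stroke_prob, self.lower_half_prior):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")


@dataclass
class SynthImage:
    """A generated image with its exact ground truth."""

    image: LegImage
    scene_label: str
    concept_canvas: np.ndarray  # (H, W) int, 0 = unpainted
    patch_labels: dict[int, np.ndarray] = field(default_factory=dict)


def _leg_mask() -> np.ndarray:
    """Tapered leg silhouette: wide thigh narrowing toward the ankle."""
    rows = np.arange(H)
    t = np.clip((rows - 20) / (H - 60), 0.0, 1.0)
    half_width = 100.0 - 52.0 * t  # 100 px at the thigh, 48 px at the ankle
    mask = np.zeros((H, W), dtype=bool)
    inside_rows = (rows >= 20) & (rows <= H - 20)
    cols = np.arange(W)
    mask[inside_rows] = (
        np.abs(cols[None, :] - W / 2.0) <= half_width[inside_rows, None]
    )
    return mask


def _random_walk(rng: np.random.Generator, start, n_steps: int,
                 step: float, wobble: float) -> np.ndarray:
    """Smooth 2-D random walk used for vessel centerlines."""
    pos = np.array(start, dtype=np.float64)
    heading = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    for _ in range(n_steps):
        heading += rng.normal(0.0, wobble)
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        pos[0] = np.clip(pos[0], 0, H - 1)
        pos[1] = np.clip(pos[1], 0, W - 1)
        pts.append(pos.copy())
    return np.array(pts)


def _paint_curve(canvas: np.ndarray, pts: np.ndarray, width: int,
                 concept: int) -> None:
    yy, xx = np.mgrid[0:2 * width + 1, 0:2 * width + 1] - width
    disk = (yy ** 2 + xx ** 2) <= width ** 2
    dy, dx = np.nonzero(disk)
    dy, dx = dy - width, dx - width
    # densify the polyline so strokes are gapless
    seg = np.repeat(pts, 3, axis=0)
    seg = (seg[:-1] + np.diff(seg, axis=0) * 0.5)
    for y, x in np.vstack([pts, seg]):
        ys = np.clip(np.rint(y + dy).astype(int), 0, H - 1)
        xs = np.clip(np.rint(x + dx).astype(int), 0, W - 1)
        canvas[ys, xs] = concept


def _paint_blob(canvas: np.ndarray, rng: np.random.Generator, center,
                radius: float, concept: int, n_lobes: int = 5) -> None:
    """Irregular blob: union of jittered disks around a center."""
    cy, cx = center
    for _ in range(n_lobes):
        oy = cy + rng.normal(0, radius * 0.45)
        ox = cx + rng.normal(0, radius * 0.45)
        r = radius * rng.uniform(0.5, 0.9)
        y0, y1 = int(max(0, oy - r)), int(min(H, oy + r + 1))
        x0, x1 = int(max(0, ox - r)), int(min(W, ox + r + 1))
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        canvas[y0:y1, x0:x1][(yy - oy) ** 2 + (xx - ox) ** 2 <= r ** 2] = concept


def _lesion_center(rng: np.random.Generator, mask: np.ndarray,
                   lower_prior: float) -> tuple[float, float]:
    lower = rng.random() < lower_prior
    rows = np.arange(H)
    ok = mask.any(axis=1)
    ok &= (rows >= H // 2) if lower else (rows < H // 2)
    row = int(rng.choice(np.flatnonzero(ok)))
    cols = np.flatnonzero(mask[row])
    return float(row), float(rng.choice(cols))


def patch_labels_from_canvas(canvas: np.ndarray, patch_size: int) -> np.ndarray:
    """Ground-truth concept per grid patch: plurality of painted pixels.

    Ties break toward the lower concept number; a patch with no painted
    pixels is concept 1 (normal skin). Returns an (n_rows, n_cols) array.
    """
    spec = GridSpec.for_scale(patch_size, canvas.shape[0], canvas.shape[1])
    p = patch_size
    crop = canvas[: spec.n_rows * p, : spec.n_cols * p]
    blocks = crop.reshape(spec.n_rows, p, spec.n_cols, p)
    labels = np.ones((spec.n_rows, spec.n_cols), dtype=np.intp)
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            counts = np.bincount(blocks[r, :, c, :].ravel(), minlength=6)
            counts[0] = 0
            if counts.sum() > 0:
                labels[r, c] = int(np.argmax(counts))  # first max: lower wins
    return labels


def generate_leg_image(scene: str, spec: SynthSpec,
                       rng: np.random.Generator,
                       image_id: str = "") -> SynthImage:
    """Generate one leg image of the given severity with ground truth."""
    if scene not in ("mild", "moderate", "severe"):
        raise ValidationError(f"unknown scene label {scene!r}")
    mask = _leg_mask()
    canvas = np.zeros((H, W), dtype=np.intp)

    if scene == "mild":
        if rng.random() < spec.mild_stroke_prob:
            for _ in range(rng.integers(3, 8)):
                start = _lesion_center(rng, mask, lower_prior=0.35)
                pts = _random_walk(rng, start, n_steps=rng.integers(25, 60),
                                   step=3.0, wobble=0.45)
                _paint_curve(canvas, pts, int(rng.integers(*spec.thin_width)) ,
                             concept=2)
    elif scene == "moderate":
        for _ in range(rng.integers(2, 4)):
            start = _lesion_center(rng, mask, lower_prior=0.5)
            pts = _random_walk(rng, start, n_steps=rng.integers(30, 70),
                               step=4.0, wobble=0.35)
            _paint_curve(canvas, pts, int(rng.integers(*spec.thick_width)),
                         concept=3)
    else:  # severe
        kinds = ((4,), (5,), (4, 5))[rng.integers(0, 3)]
        for concept in kinds:
            for _ in range(rng.integers(1, 3)):
                center = _lesion_center(rng, mask, spec.lower_half_prior)
                radius = rng.uniform(28, 48) if concept == 4 else rng.uniform(16, 30)
                _paint_blob(canvas, rng, center, radius, concept)

    canvas[~mask] = 0  # lesions exist only on the leg

    pixels = np.empty((H, W, 3), dtype=np.float64)
    base_noise = rng.normal(0.0, spec.skin_noise_sd, size=(H, W))
    shading = gaussian_filter(rng.normal(0.0, 8.0, size=(H, W)), sigma=40)
    for c in range(3):
        pixels[..., c] = SKIN_RGB[c] + base_noise + shading
    for concept, rgb in CONCEPT_RGB.items():
        sel = canvas == concept
        for c in range(3):
            pixels[..., c][sel] = rgb[c] + base_noise[sel] * 0.6
    for c in range(3):
        pixels[..., c][~mask] = BACKGROUND_RGB[c] + base_noise[~mask] * 0.4
    pixels = np.clip(pixels, 0, 255)

    img = LegImage(pixels=pixels, mask=mask, id=image_id or f"synth_{scene}")
    patch_labels = {
        s: patch_labels_from_canvas(canvas, s) for s in DEFAULT_SCALES
    }
    return SynthImage(img, scene, canvas, patch_labels)


def generate_dataset(spec: SynthSpec) -> list[SynthImage]:
    """Class-balanced synthetic dataset: 3 * n_per_class images."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for k in range(spec.n_per_class):
        for scene in ("mild", "moderate", "severe"):
            out.append(generate_leg_image(
                scene, spec, rng, image_id=f"synth_{scene}_{k:03d}"))
    return out


def write_dataset(images: list[SynthImage], out_dir,
                  scales=DEFAULT_SCALES) -> Path:
    """Persist a synthetic dataset in the real-data manifest format.

    Writes PNG images and masks, ``manifest.csv`` (image_path, mask_path,
    scene_label) and one ``patch_labels_<scale>.csv`` per scale with
    columns image_id, scale, row, col, region, foreground_fraction,
    concept_label. Returns the manifest path.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "mask_path", "scene_label"])
        for si in images:
            ip = f"images/{si.image.id}.png"
            mp = f"masks/{si.image.id}.png"
            save_image(si.image, out_dir / ip, out_dir / mp)
            writer.writerow([ip, mp, si.scene_label])
    for s in scales:
        with open(out_dir / f"patch_labels_{s}.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_id", "scale", "row", "col", "region",
                             "foreground_fraction", "concept_label"])
            for si in images:
                grid = divide(si.image, s)
                labels = si.patch_labels[s]
                for p in grid:
                    writer.writerow([
                        si.image.id, s, p.row_index, p.col_index, p.region,
                        f"{p.foreground_fraction:.4f}",
                        int(labels[p.row_index, p.col_index]),
                    ])
    return manifest_path
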
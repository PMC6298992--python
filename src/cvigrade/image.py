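"""Loading, masking and normalization of lower-limb photographs.

Images are carried through the pipeline in a canonical geometry of 250
columns x 700 rows (portrait leg crop). Pixels are held as floating point
in [0, 255] and only quantized on export; masks are boolean foreground
maps (the leg silhouette) supplied alongside the photograph or assumed
all-foreground when absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

#: canonical (width, height) of a preprocessed leg image
CANONICAL_WIDTH = 250
CANONICAL_HEIGHT = 700


class ValidationError(ValueError):
    """Raised when an input violates a pipeline contract."""


@dataclass
class LegImage:
    """A leg photograph with its foreground mask.

    Attributes
    ----------
    pixels : (H, W, 3) float array, RGB in [0, 255]
    mask : (H, W) bool array, True on the leg
    id : opaque identifier string
    """

    pixels: np.ndarray
    mask: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"pixels must be (H, W, 3), got {self.pixels.shape}"
            )
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match image "
                f"shape {self.pixels.shape[:2]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the image."""
        return self.pixels.shape[:2]

    @property
    def is_canonical(self) -> bool:
        return self.shape == (CANONICAL_HEIGHT, CANONICAL_WIDTH)


def load_image(path, mask_path=None, image_id: str | None = None) -> LegImage:
    """Read a PNG/JPEG photograph and optional single-channel mask.

    The returned channel order is always R, G, B. When ``mask_path`` is
    absent the mask is all-foreground.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    raw = raw[..., :3]  # drop alpha

    if mask_path is not None:
        try:
            mraw = iio.imread(Path(mask_path))
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read mask file {mask_path}: {exc}") from exc
        if mraw.ndim > 2:
            mraw = mraw[..., 0]
        if mraw.shape != raw.shape[:2]:
            raise ValidationError(
                f"mask shape {mraw.shape} does not match image shape "
                f"{raw.shape[:2]} ({path})"
            )
        mask = mraw > 0
    else:
        mask = np.ones(raw.shape[:2], dtype=bool)
    return LegImage(pixels=raw, mask=mask, id=image_id or path.stem)


def resize_to_canonical(img: LegImage) -> LegImage:
    """Resize to the canonical 250 x 700 frame.

    Pixels are interpolated bilinearly, the mask with nearest-neighbor.
    Aspect ratio is not preserved: the canonical frame encodes the
    typical leg length-to-width ratio.
    """
    if img.pixels.size == 0:
        raise ValidationError("cannot resize an empty image")
    if img.is_canonical:
        return img
    out_shape = (CANONICAL_HEIGHT, CANONICAL_WIDTH)
    pixels = resize(
        img.pixels, out_shape, order=1, preserve_range=True,
        anti_aliasing=False,
    ).astype(np.float32)
    mask = resize(
        img.mask.astype(np.uint8), out_shape, order=0, preserve_range=True,
        anti_aliasing=False,
    ).astype(bool)
    if not mask.any():
        raise ValidationError(f"mask of image {img.id!r} is empty after resize")
    return LegImage(pixels=pixels, mask=mask, id=img.id)


def gray_world_normalize(img: LegImage) -> LegImage:
    """Gray-world color-constancy correction over foreground pixels.

    Each channel is scaled so that the three foreground channel means
    coincide at their common mean; the result is clipped to [0, 255].
    Background pixels are scaled by the same factors but do not influence
    them. The mask is unchanged.
    """
    if not img.mask.any():
        raise ValidationError("gray-world normalization needs foreground pixels")
    fg = img.pixels[img.mask]  # (n, 3)
    means = fg.mean(axis=0, dtype=np.float64)
    if np.any(means <= 0):
        raise ValidationError(
            "degenerate image: a channel has zero foreground mean"
        )
    target = means.mean()
    factors = (target / means).astype(np.float32)
    pixels = np.clip(img.pixels * factors, 0.0, 255.0)
    return LegImage(pixels=pixels, mask=img.mask.copy(), id=img.id)


def preprocess(img: LegImage) -> LegImage:
    """Full preprocessing chain: resize to canonical, then gray-world."""
    return gray_world_normalize(resize_to_canonical(img))


def save_image(img: LegImage, path, mask_path=None) -> None:
    """Write pixels (and optionally the mask) as 8-bit PNG."""
    iio.imwrite(Path(path), np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8))
    if mask_path is not None:
        iio.imwrite(Path(mask_path), (img.mask.astype(np.uint8) * 255))


def load_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV.

    Columns: ``image_path``, ``mask_path`` (may be empty), ``scene_label``.
    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"image_path", "mask_path", "scene_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest {path} lacks columns {sorted(missing)}")
    base = path.parent

    def _resolve(p: str) -> str:
        return "" if p == "" else str((base / p) if not Path(p).is_absolute() else Path(p))

    df["image_path"] = df["image_path"].map(_resolve)
    df["mask_path"] = df["mask_path"].map(_resolve)
    return df


def load_manifest_images(manifest: pd.DataFrame) -> list[LegImage]:
    """Load and preprocess every image referenced by a manifest."""
    images = []
    for _, row in manifest.iterrows():
        img = load_image(
            row["image_path"], row["mask_path"] or None
        )
        images.append(preprocess(img))
    return images
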
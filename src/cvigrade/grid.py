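"""Regular-grid patch division of canonical leg images.

A canonical 250 x 700 image is cut into square patches at one of the
divided scales (15, 25 or 50 px by default). Pixels beyond the largest
multiple of the patch size are cropped at the right/bottom edge, so no
partial patches exist. Each patch is tagged with the spatial region
(upper or lower half of the leg, split at the image midline, row 350)
and with the fraction of foreground pixels under its window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import CANONICAL_HEIGHT, CANONICAL_WIDTH, LegImage, ValidationError

#: grid scales used by the multi-scale representation, in fixed order
DEFAULT_SCALES: tuple[int, ...] = (15, 25, 50)

#: row index of the upper/lower split in the canonical frame
MIDLINE_ROW = CANONICAL_HEIGHT // 2

UPPER = "upper"
LOWER = "lower"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of one regular grid over the canonical frame."""

    patch_size: int
    n_rows: int
    n_cols: int

    @classmethod
    def for_scale(cls, patch_size: int,
                  height: int = CANONICAL_HEIGHT,
                  width: int = CANONICAL_WIDTH) -> "GridSpec":
        if patch_size <= 0:
            raise ValidationError(f"patch_size must be positive, got {patch_size}")
        if patch_size > height or patch_size > width:
            raise ValidationError(
                f"patch_size {patch_size} exceeds image dimensions "
                f"{height}x{width}"
            )
        return cls(patch_size, height // patch_size, width // patch_size)

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class Patch:
    """One grid cell: 0-based grid coordinates and half-open pixel window."""

    row_index: int
    col_index: int
    y0: int
    y1: int
    x0: int
    x1: int
    region: str
    foreground_fraction: float

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) pixel coordinates of the patch center."""
        return ((self.y0 + self.y1 - 1) / 2.0, (self.x0 + self.x1 - 1) / 2.0)

    def window(self, arr: np.ndarray) -> np.ndarray:
        """View of ``arr`` restricted to this patch."""
        return arr[self.y0:self.y1, self.x0:self.x1]


def region_of_center(center_row: float, midline: float = MIDLINE_ROW) -> str:
    """Upper if the center row lies strictly above the midline, else lower."""
    return UPPER if center_row < midline else LOWER


def region_of(patch: Patch) -> str:
    """Spatial region of a patch, decided solely by its center row."""
    return region_of_center(patch.center[0])


def divide(img: LegImage, patch_size: int) -> list[Patch]:
    """Cut an image into a regular grid of square patches.

    Returns the patches in row-major order. The right/bottom strip of
    pixels that does not fill a whole patch is discarded.
    """
    height, width = img.shape
    if patch_size > height or patch_size > width:
        raise ValidationError(
            f"patch_size {patch_size} exceeds image dimensions {height}x{width}"
        )
    spec = GridSpec(patch_size, height // patch_size, width // patch_size)

    # per-patch foreground fractions, vectorized over the whole grid
    crop = img.mask[: spec.n_rows * patch_size, : spec.n_cols * patch_size]
    frac = crop.reshape(
        spec.n_rows, patch_size, spec.n_cols, patch_size
    ).mean(axis=(1, 3))

    patches = []
    for r in range(spec.n_rows):
        y0 = r * patch_size
        for c in range(spec.n_cols):
            x0 = c * patch_size
            center_row = y0 + (patch_size - 1) / 2.0
            patches.append(Patch(
                row_index=r, col_index=c,
                y0=y0, y1=y0 + patch_size, x0=x0, x1=x0 + patch_size,
                region=region_of_center(center_row),
                foreground_fraction=float(frac[r, c]),
            ))
    return patches


def grid_spec_of(patches: list[Patch]) -> GridSpec:
    """Recover the GridSpec of a row-major patch list."""
    if not patches:
        raise ValidationError("empty patch collection")
    size = patches[0].y1 - patches[0].y0
    n_rows = max(p.row_index for p in patches) + 1
    n_cols = max(p.col_index for p in patches) + 1
    return GridSpec(size, n_rows, n_cols)


def filter_foreground(patches: list[Patch], min_fraction: float = 0.5) -> list[Patch]:
    """Keep patches whose foreground fraction reaches ``min_fraction``."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValidationError(f"min_fraction must be in [0, 1], got {min_fraction}")
    return [p for p in patches if p.foreground_fraction >= min_fraction]
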
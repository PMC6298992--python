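"""Per-patch texture, color and context descriptors.

Every patch of a grid is described by a fixed-layout concatenation of
descriptor blocks:

==============  ======  =====================================================
block           length  content
==============  ======  =====================================================
lbp             59      uniform LBP histogram (radius 1, 8 neighbors)
ehd             5       MPEG-7 edge-type histogram (2x2 sub-blocks)
glcm            4       contrast, correlation, energy, homogeneity (16 gray
                        levels, 4 symmetric unit offsets, averaged)
sift_stats      256     elementwise mean and variance of dense 128-dim
                        gradient-orientation descriptors inside the patch
grad_mean       1       mean gradient magnitude
color_stats     18      mean, median, variance per channel, RGB and YCbCr
context         7       mean 4-neighbor summary (grad_mean + 6 color means)
patch_index     2       (row, col) grid position normalized to [0, 1]
==============  ======  =====================================================

Total length 352, identical for every patch of a scale. Intensities are
floats in [0, 255]; grayscale is the BT.601 luma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import local_binary_pattern

from .grid import GridSpec, Patch, grid_spec_of
from .image import LegImage, ValidationError

N_LBP_BINS = 59  # uniform patterns P=8: 58 uniform + 1 non-uniform bin
N_EHD_BINS = 5
N_GLCM_STATS = 4
N_SIFT_STATS = 256
N_COLOR_STATS = 18
N_CONTEXT = 7

EHD_THRESHOLD = 11.0  # MPEG-7 default edge-strength threshold
GLCM_LEVELS = 16
SIFT_STEP = 4
SIFT_ORI_BINS = 8
SIFT_GRID = 4  # 4x4 spatial cells -> 128-dim descriptor


@dataclass(frozen=True)
class FeatureLayout:
    """Named blocks with offsets into the flat feature vector."""

    blocks: tuple[tuple[str, int], ...] = (
        ("lbp", N_LBP_BINS),
        ("ehd", N_EHD_BINS),
        ("glcm", N_GLCM_STATS),
        ("sift_stats", N_SIFT_STATS),
        ("grad_mean", 1),
        ("color_stats", N_COLOR_STATS),
        ("context", N_CONTEXT),
        ("patch_index", 2),
    )

    @property
    def length(self) -> int:
        return sum(n for _, n in self.blocks)

    def offsets(self) -> dict[str, tuple[int, int]]:
        """Half-open [start, stop) ranges per block."""
        out, pos = {}, 0
        for name, n in self.blocks:
            out[name] = (pos, pos + n)
            pos += n
        return out

    def slice(self, name: str) -> slice:
        start, stop = self.offsets()[name]
        return slice(start, stop)


LAYOUT = FeatureLayout()


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB array in [0, 255]."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    """Full-range BT.601 YCbCr of an RGB array in [0, 255]."""
    rgb = np.asarray(rgb, dtype=np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168735892 * r - 0.331264108 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418687589 * g - 0.081312411 * b
    return np.stack([y, cb, cr], axis=-1)


# --------------------------------------------------------------------------
# individual descriptor blocks
# --------------------------------------------------------------------------

def lbp_histogram(window: np.ndarray) -> np.ndarray:
    """Normalized histogram of uniform LBP codes (P=8, R=1), 59 bins."""
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2 or min(window.shape) < 3:
        raise ValidationError(
            f"LBP needs a 2-D window of at least 3x3, got {window.shape}"
        )
    # integer intensities: LBP neighbor comparisons are unstable on floats
    codes = local_binary_pattern(
        np.rint(window).astype(np.int64), P=8, R=1, method="nri_uniform")
    # border codes depend on zero padding; keep the valid interior only
    hist = np.bincount(
        codes[1:-1, 1:-1].astype(np.intp).ravel(), minlength=N_LBP_BINS)
    return hist / hist.sum()


# MPEG-7 edge filter coefficients for the (a, b, c, d) pixels of a 2x2
# sub-block laid out as [[a, b], [c, d]].
_EHD_FILTERS = np.array([
    [1.0, -1.0, 1.0, -1.0],                # vertical
    [1.0, 1.0, -1.0, -1.0],                # horizontal
    [np.sqrt(2.0), 0.0, 0.0, -np.sqrt(2.0)],   # 45 degrees
    [0.0, np.sqrt(2.0), -np.sqrt(2.0), 0.0],   # 135 degrees
    [2.0, -2.0, -2.0, 2.0],                # non-directional
])


def edge_histogram(window: np.ndarray,
                   threshold: float = EHD_THRESHOLD) -> np.ndarray:
    """Five-bin MPEG-7 edge-type histogram over 2x2 sub-blocks.

    Sub-blocks whose strongest filter response stays below ``threshold``
    vote for no bin; the histogram is renormalized to sum to 1, or
    all-zero when no sub-block qualifies.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2 or min(window.shape) < 2:
        raise ValidationError(
            f"EHD needs a 2-D window of at least 2x2, got {window.shape}"
        )
    q0, q1 = window.shape[0] // 2, window.shape[1] // 2
    w = window[: 2 * q0, : 2 * q1].reshape(q0, 2, q1, 2)
    abcd = np.stack(
        [w[:, 0, :, 0], w[:, 0, :, 1], w[:, 1, :, 0], w[:, 1, :, 1]], axis=-1
    )  # (q0, q1, 4)
    strengths = np.abs(abcd @ _EHD_FILTERS.T)  # (q0, q1, 5)
    best = strengths.argmax(axis=-1)
    strong = strengths.max(axis=-1) >= threshold
    hist = np.bincount(best[strong].ravel(), minlength=N_EHD_BINS).astype(float)
    total = hist.sum()
    return hist / total if total > 0 else hist


_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def glcm_stats(window: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Contrast, correlation, energy, homogeneity of the co-occurrence matrix.

    Intensities are quantized to ``levels`` equal bins over [0, 255]; the
    four unit offsets are counted symmetrically and the statistics are
    averaged over offsets. A constant window has zero variance, for which
    correlation is defined as 0.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2 or min(window.shape) < 2:
        raise ValidationError(
            f"GLCM needs a 2-D window of at least 2x2, got {window.shape}"
        )
    q = np.clip((window * (levels / 256.0)).astype(np.intp), 0, levels - 1)
    idx = np.arange(levels, dtype=np.float64)
    ii = idx[:, None]
    jj = idx[None, :]
    diff2 = (ii - jj) ** 2
    homog_w = 1.0 / (1.0 + np.abs(ii - jj))

    stats = np.zeros(4)
    for dy, dx in _GLCM_OFFSETS:
        a = q[max(0, -dy): q.shape[0] - max(0, dy),
              max(0, -dx): q.shape[1] - max(0, dx)]
        b = q[max(0, dy):, max(0, dx):][: a.shape[0], : a.shape[1]]
        counts = np.bincount(
            (a * levels + b).ravel(), minlength=levels * levels
        ).reshape(levels, levels).astype(np.float64)
        counts = counts + counts.T  # symmetric
        p = counts / counts.sum()
        contrast = float((p * diff2).sum())
        energy = float((p ** 2).sum())
        homogeneity = float((p * homog_w).sum())
        mu_i = float((p.sum(axis=1) * idx).sum())
        mu_j = float((p.sum(axis=0) * idx).sum())
        var_i = float((p.sum(axis=1) * (idx - mu_i) ** 2).sum())
        var_j = float((p.sum(axis=0) * (idx - mu_j) ** 2).sum())
        if var_i > 0 and var_j > 0:
            corr = float(((ii - mu_i) * (jj - mu_j) * p).sum()
                         / np.sqrt(var_i * var_j))
        else:
            corr = 0.0
        stats += (contrast, corr, energy, homogeneity)
    return stats / len(_GLCM_OFFSETS)


def _sift_cell_size(patch_size: int) -> int:
    # descriptor spans SIFT_GRID cells; scale the cell to the patch so the
    # smallest scale (15 px) still fits a whole descriptor
    return max(2, patch_size // 5)


def _dense_sift_descriptors(window: np.ndarray,
                            step: int = SIFT_STEP) -> np.ndarray:
    """All 128-dim descriptors on the dense site grid inside the window."""
    window = np.asarray(window, dtype=np.float64)
    size = min(window.shape)
    cell = _sift_cell_size(size)
    span = SIFT_GRID * cell
    gy, gx = np.gradient(window)
    mag = np.hypot(gy, gx)
    ori = np.arctan2(gy, gx)  # [-pi, pi]
    obin = np.floor((ori + np.pi) / (2 * np.pi) * SIFT_ORI_BINS).astype(np.intp)
    obin = np.clip(obin, 0, SIFT_ORI_BINS - 1)

    # local-cell index template for one descriptor window
    local = np.arange(span)
    cell_id = np.minimum(local // cell, SIFT_GRID - 1)
    cell_idx = (cell_id[:, None] * SIFT_GRID + cell_id[None, :])  # (span, span)

    descs = []
    ys = range(0, window.shape[0] - span + 1, step)
    xs = range(0, window.shape[1] - span + 1, step)
    for y in ys:
        for x in xs:
            m = mag[y:y + span, x:x + span]
            o = obin[y:y + span, x:x + span]
            flat = cell_idx * SIFT_ORI_BINS + o
            d = np.bincount(flat.ravel(), weights=m.ravel(),
                            minlength=SIFT_GRID * SIFT_GRID * SIFT_ORI_BINS)
            norm = np.linalg.norm(d)
            if norm > 0:
                d = np.minimum(d / norm, 0.2)
                norm = np.linalg.norm(d)
                if norm > 0:
                    d = d / norm
            descs.append(d)
    return np.array(descs)


def dense_sift_stats(window: np.ndarray) -> np.ndarray:
    """Elementwise mean and variance of dense descriptors (256 values)."""
    window = np.asarray(window, dtype=np.float64)
    cell = _sift_cell_size(min(window.shape))
    if min(window.shape) < SIFT_GRID * cell:
        raise ValidationError(
            f"window {window.shape} too small for a dense descriptor"
        )
    descs = _dense_sift_descriptors(window)
    mean = descs.mean(axis=0)
    var = descs.var(axis=0)  # single site -> exactly zero
    return np.concatenate([mean, var])


def gradient_mean(window: np.ndarray) -> float:
    """Mean gradient magnitude (central differences, one-sided at borders)."""
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2 or min(window.shape) < 2:
        raise ValidationError(
            f"gradient needs a 2-D window of at least 2x2, got {window.shape}"
        )
    gy, gx = np.gradient(window)
    return float(np.hypot(gy, gx).mean())


def color_stats(window: np.ndarray) -> np.ndarray:
    """Mean, median, variance per channel in RGB and YCbCr (18 values)."""
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 3 or window.shape[2] != 3:
        raise ValidationError(
            f"color stats need a 3-channel window, got {window.shape}"
        )
    out = []
    for space in (window, rgb_to_ycbcr(window)):
        flat = space.reshape(-1, 3)
        for c in range(3):
            v = flat[:, c]
            out.extend([v.mean(), float(np.median(v)), v.var()])
    return np.array(out)


def patch_summary(window_rgb: np.ndarray) -> np.ndarray:
    """7-value neighbor summary: gradient mean + RGB and YCbCr channel means."""
    gray = rgb_to_gray(window_rgb)
    rgb_means = np.asarray(window_rgb, dtype=np.float64).reshape(-1, 3).mean(axis=0)
    ycc_means = rgb_to_ycbcr(window_rgb).reshape(-1, 3).mean(axis=0)
    return np.concatenate([[gradient_mean(gray)], rgb_means, ycc_means])


def context_features(patch: Patch, patches: list[Patch],
                     summaries: np.ndarray,
                     included: np.ndarray | None = None) -> np.ndarray:
    """Mean summary of the 4-connected neighbors of a patch.

    ``summaries`` is the (n_patches, 7) matrix of :func:`patch_summary`
    rows aligned with ``patches`` (row-major). Neighbors outside the grid
    or excluded by the foreground filter (``included`` false) do not
    contribute; with no contributing neighbor the context is all zeros.
    """
    spec = grid_spec_of(patches)
    if included is None:
        included = np.ones(len(patches), dtype=bool)
    acc, count = np.zeros(N_CONTEXT), 0
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        r, c = patch.row_index + dr, patch.col_index + dc
        if 0 <= r < spec.n_rows and 0 <= c < spec.n_cols:
            k = r * spec.n_cols + c
            if included[k]:
                acc += summaries[k]
                count += 1
    return acc / count if count else acc


def assemble(patch: Patch, blocks: dict[str, np.ndarray],
             spec: GridSpec, layout: FeatureLayout = LAYOUT) -> np.ndarray:
    """Concatenate descriptor blocks in the fixed layout.

    The patch_index block is derived here from the patch coordinates,
    normalized by the grid dimensions so it is comparable across scales.
    """
    blocks = dict(blocks)
    blocks["patch_index"] = np.array([
        patch.row_index / spec.n_rows, patch.col_index / spec.n_cols,
    ])
    parts = []
    for name, n in layout.blocks:
        if name not in blocks:
            raise ValidationError(f"missing feature block {name!r}")
        arr = np.atleast_1d(np.asarray(blocks[name], dtype=np.float64))
        if arr.size != n:
            raise ValidationError(
                f"block {name!r} has size {arr.size}, expected {n}"
            )
        parts.append(arr)
    vec = np.concatenate(parts)
    if not np.all(np.isfinite(vec)):
        raise ValidationError("feature vector contains non-finite entries")
    return vec


def compute_feature_matrix(img: LegImage, patches: list[Patch],
                           included: np.ndarray | None = None,
                           layout: FeatureLayout = LAYOUT) -> np.ndarray:
    """Feature matrix for a row-major patch grid of one image.

    ``included`` marks the patches that pass the foreground filter; the
    context block only draws on included neighbors. Rows are returned for
    every patch (callers typically keep the included ones).
    """
    spec = grid_spec_of(patches)
    gray = rgb_to_gray(img.pixels)
    n = len(patches)
    if included is None:
        included = np.ones(n, dtype=bool)

    summaries = np.zeros((n, N_CONTEXT))
    for k, p in enumerate(patches):
        summaries[k] = patch_summary(p.window(img.pixels))

    rows = np.zeros((n, layout.length))
    for k, p in enumerate(patches):
        if not included[k]:
            continue
        g = p.window(gray)
        rgbw = p.window(img.pixels)
        blocks = {
            "lbp": lbp_histogram(g),
            "ehd": edge_histogram(g),
            "glcm": glcm_stats(g),
            "sift_stats": dense_sift_stats(g),
            "grad_mean": gradient_mean(g),
            "color_stats": color_stats(rgbw),
            "context": context_features(p, patches, summaries, included),
        }
        rows[k] = assemble(p, blocks, spec, layout)
    return rows
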
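"""Concept-occurrence vectors and the multi-scale region-wise representation.

A set of patch concept labels is summarized by its concept-occurrence
vector (COV): the normalized 5-bin histogram of concepts. An image is
represented region-wise at one grid scale by concatenating the COVs of
the whole image, the upper half and the lower half (15 values), and the
final representation concatenates the region-wise vectors of the three
scales in the fixed order (15, 25, 50) for 45 values in total.
"""

from __future__ import annotations

import numpy as np

from .grid import DEFAULT_SCALES, LOWER, UPPER
from .image import ValidationError

N_CONCEPTS = 5
N_REGION_BLOCKS = 3  # whole, upper, lower
REGION_DIM = N_CONCEPTS * N_REGION_BLOCKS  # 15
SCENE_DIM = REGION_DIM * len(DEFAULT_SCALES)  # 45


def concept_occurrence_vector(labels) -> np.ndarray:
    """Normalized histogram of concept labels 1..5; zeros when empty."""
    labels = np.asarray(list(labels), dtype=np.intp)
    if labels.size == 0:
        return np.zeros(N_CONCEPTS)
    if labels.min() < 1 or labels.max() > N_CONCEPTS:
        raise ValidationError(
            f"concept labels must lie in 1..{N_CONCEPTS}"
        )
    counts = np.bincount(labels - 1, minlength=N_CONCEPTS).astype(np.float64)
    return counts / counts.sum()


def region_wise_representation(labels, regions) -> np.ndarray:
    """Concatenated (whole, upper, lower) COVs of one image at one scale."""
    labels = np.asarray(list(labels), dtype=np.intp)
    regions = np.asarray(list(regions))
    if labels.shape != regions.shape:
        raise ValidationError("labels and regions must align")
    whole = concept_occurrence_vector(labels)
    upper = concept_occurrence_vector(labels[regions == UPPER])
    lower = concept_occurrence_vector(labels[regions == LOWER])
    return np.concatenate([whole, upper, lower])


def multiscale_representation(per_scale: dict[int, np.ndarray],
                              scales=DEFAULT_SCALES) -> np.ndarray:
    """Concatenate region-wise vectors over the scales in fixed order."""
    parts = []
    for s in scales:
        if s not in per_scale:
            raise ValidationError(f"missing region-wise vector for scale {s}")
        v = np.asarray(per_scale[s], dtype=np.float64)
        if v.shape != (REGION_DIM,):
            raise ValidationError(
                f"region-wise vector for scale {s} has shape {v.shape}, "
                f"expected ({REGION_DIM},)"
            )
        parts.append(v)
    return np.concatenate(parts)


def representation_layout(scales=DEFAULT_SCALES) -> dict[str, tuple[int, int]]:
    """Half-open offset ranges of each (scale, region) block."""
    out, pos = {}, 0
    for s in scales:
        for region in ("whole", UPPER, LOWER):
            out[f"scale{s}_{region}"] = (pos, pos + N_CONCEPTS)
            pos += N_CONCEPTS
    return out
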
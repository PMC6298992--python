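"""End-to-end orchestration: features -> concepts -> representation -> scene.

The full chain at the defaults mirrors the intended use: canonical
images are divided at the three scales, per-patch features are
extracted, one concept SVM per scale maps patches to concepts, the
concept labels are pooled into the 45-dim multi-scale region-wise
representation, and the scene SVM (with per-repeat fuzzy-entropy
feature selection) grades severity under a repeated stratified
hold-out protocol. A k-means visual-codebook baseline replaces the
supervised concept stage for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import metrics, representation, selection
from .grid import DEFAULT_SCALES, divide, filter_foreground
from .image import LegImage, ValidationError
from .features import LAYOUT, compute_feature_matrix
from .models import (ConceptModel, predict_concepts, train_concept_classifier,
                     train_scene_classifier)


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline."""

    scales: tuple[int, ...] = DEFAULT_SCALES
    min_foreground_fraction: float = 0.5
    svm_c: float = 1.0
    #: per-class cap on concept-training patches (keeps SVM training tractable)
    max_patches_per_class: int = 250
    #: repeats of the concept train/validation split; the best model is kept
    n_concept_repeats: int = 3
    concept_train_fraction: float = 2.0 / 3.0
    #: scene-stage protocol
    n_repeats: int = 20
    train_fraction: float = 2.0 / 3.0
    scene_feature_selection: bool = True
    selection_k_max: int | None = None
    selection_beta: float = selection.DEFAULT_BETA
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValidationError("scales must be a nonempty positive list")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")


@dataclass
class PatchTable:
    """Foreground patches of one scale across a whole image collection."""

    scale: int
    image_index: np.ndarray   # (n_patches,)
    regions: np.ndarray       # (n_patches,) of "upper"/"lower"
    features: np.ndarray      # (n_patches, d) float32
    gt_labels: np.ndarray | None = None   # ground-truth concepts, if known
    pred_labels: np.ndarray | None = None


def extract_patch_table(images: list[LegImage], scale: int,
                        config: PipelineConfig,
                        gt_label_grids: list[np.ndarray] | None = None,
                        ) -> PatchTable:
    """Divide, filter and describe every image at one scale."""
    idx_parts, region_parts, feat_parts, gt_parts = [], [], [], []
    for i, img in enumerate(images):
        patches = divide(img, scale)
        kept_list = filter_foreground(patches, config.min_foreground_fraction)
        kept_set = {(p.row_index, p.col_index) for p in kept_list}
        included = np.array(
            [(p.row_index, p.col_index) in kept_set for p in patches])
        feats = compute_feature_matrix(img, patches, included)
        feat_parts.append(feats[included].astype(np.float32))
        idx_parts.append(np.full(len(kept_list), i, dtype=np.intp))
        region_parts.append(np.array([p.region for p in kept_list]))
        if gt_label_grids is not None:
            g = gt_label_grids[i]
            gt_parts.append(np.array(
                [g[p.row_index, p.col_index] for p in kept_list], dtype=np.intp))
    return PatchTable(
        scale=scale,
        image_index=np.concatenate(idx_parts),
        regions=np.concatenate(region_parts),
        features=np.vstack(feat_parts),
        gt_labels=np.concatenate(gt_parts) if gt_parts else None,
    )


def _balanced_subsample(labels: np.ndarray, cap: int,
                        rng: np.random.Generator) -> np.ndarray:
    keep = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def train_concept_model(table: PatchTable, config: PipelineConfig,
                        rng: np.random.Generator,
                        selected=None) -> tuple[ConceptModel, float]:
    """Train the concept SVM for one scale; keep the best of several repeats.

    Training patches are a class-balanced subsample; each repeat holds
    out a validation third and the model with the best validation
    accuracy is returned together with that accuracy.
    """
    if table.gt_labels is None:
        raise ValidationError("concept training needs ground-truth labels")
    sub = _balanced_subsample(table.gt_labels, config.max_patches_per_class, rng)
    X = table.features[sub].astype(np.float64)
    y = table.gt_labels[sub]
    best_model, best_acc = None, -1.0
    for _ in range(config.n_concept_repeats):
        tr, va = metrics.stratified_split(y, config.concept_train_fraction, rng)
        model = train_concept_classifier(
            X[tr], y[tr], selected=selected, scale=table.scale, C=config.svm_c)
        acc = float((model.predict(X[va]) == y[va]).mean())
        if acc > best_acc:
            best_model, best_acc = model, acc
    return best_model, best_acc


def predict_table_concepts(model: ConceptModel, table: PatchTable) -> None:
    table.pred_labels = predict_concepts(
        model, table.features.astype(np.float64))


def build_representations(tables: dict[int, PatchTable], n_images: int,
                          scales=DEFAULT_SCALES,
                          use_ground_truth: bool = False) -> np.ndarray:
    """(n_images, 45) multi-scale region-wise representation matrix."""
    reps = np.zeros((n_images, representation.REGION_DIM * len(scales)))
    for i in range(n_images):
        per_scale = {}
        for s in scales:
            t = tables[s]
            labels = t.gt_labels if use_ground_truth else t.pred_labels
            if labels is None:
                raise ValidationError(
                    f"scale {s}: concept labels not available yet")
            sel = t.image_index == i
            per_scale[s] = representation.region_wise_representation(
                labels[sel], t.regions[sel])
        reps[i] = representation.multiscale_representation(per_scale, scales)
    return reps


def single_scale_representations(tables: dict[int, PatchTable],
                                 n_images: int) -> dict[int, np.ndarray]:
    """15-dim region-wise representation per scale (for scale comparisons)."""
    out = {}
    for s, t in tables.items():
        reps = np.zeros((n_images, representation.REGION_DIM))
        for i in range(n_images):
            sel = t.image_index == i
            reps[i] = representation.region_wise_representation(
                t.pred_labels[sel], t.regions[sel])
        out[s] = reps
    return out


def scene_fit_predict(config: PipelineConfig):
    """fit_predict callback for the repeated-split scene protocol.

    Performs per-repeat fuzzy forward selection on the training portion
    (when enabled), fits the linear scene SVM and predicts the test
    portion. Reports the number of selected features per repeat.
    """

    def _fit_predict(X_train, y_train, X_test, rng):
        d = X_train.shape[1]
        selected = None
        if config.scene_feature_selection:
            state = selection.forward_select(
                X_train, y_train,
                k_max=config.selection_k_max or d,
                beta=config.selection_beta)
            if state.selected:
                selected = np.array(state.selected)
        model = train_scene_classifier(
            X_train, y_train, selected=selected, C=config.svm_c)
        info = {"n_selected": int(len(selected) if selected is not None else d)}
        return model.predict(X_test), info

    return _fit_predict


def evaluate_scene_protocol(reps: np.ndarray, scene_labels,
                            config: PipelineConfig,
                            feature_selection: bool | None = None) -> dict:
    """Repeated stratified 2/3-1/3 protocol on a representation matrix."""
    cfg = config
    if feature_selection is not None and feature_selection != config.scene_feature_selection:
        from dataclasses import replace
        cfg = replace(config, scene_feature_selection=feature_selection)
    return metrics.repeated_split_evaluation(
        reps, np.asarray(scene_labels), scene_fit_predict(cfg),
        n_repeats=cfg.n_repeats, train_fraction=cfg.train_fraction,
        seed=cfg.seed)


def kmeans_codebook_representations(tables: dict[int, PatchTable],
                                    n_images: int, k: int = 50,
                                    seed: int = 0,
                                    max_fit_samples: int = 4000) -> np.ndarray:
    """Unsupervised visual-codebook baseline representation.

    Per scale, a k-means codebook is fitted on (a subsample of) the patch
    features; every patch maps to its nearest word and the image is
    represented by normalized word histograms for the whole image, upper
    and lower halves, concatenated over scales (3 regions x k x n_scales
    values). This replaces the supervised concept stage.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for s in sorted(tables):
        t = tables[s]
        X = t.features.astype(np.float64)
        fit_idx = np.arange(X.shape[0])
        if fit_idx.size > max_fit_samples:
            fit_idx = rng.choice(fit_idx, size=max_fit_samples, replace=False)
        # standardize so heterogeneous blocks share the metric
        mu, sd = X[fit_idx].mean(axis=0), X[fit_idx].std(axis=0)
        sd[sd == 0] = 1.0
        km = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31)))
        km.fit((X[fit_idx] - mu) / sd)
        words = km.predict((X - mu) / sd)
        reps = np.zeros((n_images, 3 * k))
        for i in range(n_images):
            sel = t.image_index == i
            for b, region_sel in enumerate((
                    sel, sel & (t.regions == "upper"),
                    sel & (t.regions == "lower"))):
                w = words[region_sel]
                if w.size:
                    hist = np.bincount(w, minlength=k).astype(np.float64)
                    reps[i, b * k:(b + 1) * k] = hist / hist.sum()
        blocks.append(reps)
    return np.hstack(blocks)


@dataclass
class EndToEndResult:
    """Everything the full synthetic-study run produces."""

    representations: np.ndarray
    scene_labels: np.ndarray
    combined: dict
    per_scale: dict[int, dict] = field(default_factory=dict)
    concept_val_accuracy: dict[int, float] = field(default_factory=dict)
    concept_patch_accuracy: dict[int, float] = field(default_factory=dict)
    tables: dict[int, PatchTable] = field(default_factory=dict)


def run_end_to_end(images: list[LegImage], scene_labels,
                   gt_label_grids: dict[int, list[np.ndarray]],
                   config: PipelineConfig,
                   evaluate_single_scales: bool = True) -> EndToEndResult:
    """Full supervised pipeline on an annotated image collection.

    ``gt_label_grids`` maps scale -> per-image ground-truth concept grid.
    Concept models are trained per scale on a balanced patch subsample,
    all patches are classified, representations are built from the
    predicted concepts, and the scene protocol is evaluated on the
    combined 45-dim representation (and optionally per single scale).
    """
    rng = np.random.default_rng(config.seed)
    scene_labels = np.asarray(scene_labels)
    n_images = len(images)

    tables: dict[int, PatchTable] = {}
    result = EndToEndResult(np.empty(0), scene_labels, {})
    for s in config.scales:
        t = extract_patch_table(images, s, config, gt_label_grids[s])
        model, val_acc = train_concept_model(t, config, rng)
        predict_table_concepts(model, t)
        tables[s] = t
        result.concept_val_accuracy[s] = val_acc
        result.concept_patch_accuracy[s] = float(
            (t.pred_labels == t.gt_labels).mean())

    reps = build_representations(tables, n_images, config.scales)
    result.representations = reps
    result.tables = tables
    result.combined = evaluate_scene_protocol(reps, scene_labels, config)
    if evaluate_single_scales:
        for s, r in single_scale_representations(tables, n_images).items():
            result.per_scale[s] = evaluate_scene_protocol(
                r, scene_labels, config)
    return result
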
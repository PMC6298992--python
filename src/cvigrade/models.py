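"""Concept and scene classifiers, plus annotation resolution.

The concept classifier maps patch feature vectors to the five concepts
(1 normal skin, 2 reticular vein/telangiectasia, 3 varicose veins,
4 pigmentation/edema, 5 vein ulcers); one model is trained per divided
scale. The scene classifier maps the 45-dim multi-scale representation
to a severity (mild / moderate / severe). Both are one-vs-one SVMs on
standardized, optionally column-selected inputs: a quadratic polynomial
kernel for concepts, a linear kernel for scenes, C = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grid import Patch
from .image import ValidationError

CONCEPT_LABELS = (1, 2, 3, 4, 5)
CONCEPT_NAMES = {
    1: "normal skin",
    2: "reticular vein or telangiectasia",
    3: "varicose veins",
    4: "pigmentation or edema",
    5: "vein ulcers",
}
SCENE_LABELS = ("mild", "moderate", "severe")


def resolve_patch_label(annotations, patch: Patch | None = None,
                        resolved_neighbors: dict | None = None) -> int:
    """Resolve three annotators' concept labels for one patch.

    Unanimity or a 2-of-3 majority decides directly. A three-way
    disagreement inherits the label of the nearest already-resolved
    patch (Euclidean distance between patch centers; ties broken toward
    the smaller row, then smaller column). ``resolved_neighbors`` maps
    Patch -> label (or (center_row, center_col) -> label).
    """
    annotations = list(annotations)
    if len(annotations) != 3:
        raise ValidationError("exactly three annotations are required")
    for a in annotations:
        if a not in CONCEPT_LABELS:
            raise ValidationError(f"annotation {a!r} is not a concept label")
    values, counts = np.unique(annotations, return_counts=True)
    if counts.max() >= 2:
        return int(values[np.argmax(counts)])
    if not resolved_neighbors or patch is None:
        raise ValidationError(
            "three-way disagreement with no resolved neighbor to inherit from"
        )
    cy, cx = patch.center
    best = None
    for key, label in resolved_neighbors.items():
        ny, nx = key.center if isinstance(key, Patch) else key
        cand = ((ny - cy) ** 2 + (nx - cx) ** 2, ny, nx, label)
        if best is None or cand[:3] < best[:3]:
            best = cand
    return int(best[3])


def resolve_annotations(patches: list[Patch], annotation_triples) -> list[int]:
    """Resolve a whole grid of annotation triples.

    Majority patches resolve first; remaining three-way conflicts then
    inherit from the nearest resolved patch.
    """
    triples = [list(t) for t in annotation_triples]
    if len(triples) != len(patches):
        raise ValidationError("one annotation triple per patch is required")
    labels: list[int | None] = [None] * len(patches)
    resolved: dict = {}
    conflicts = []
    for k, (p, t) in enumerate(zip(patches, triples)):
        values, counts = np.unique(t, return_counts=True)
        if counts.max() >= 2:
            labels[k] = int(values[np.argmax(counts)])
            resolved[p] = labels[k]
        else:
            conflicts.append(k)
    for k in conflicts:
        labels[k] = resolve_patch_label(triples[k], patches[k], resolved)
    return labels  # type: ignore[return-value]


@dataclass
class _SvmModel:
    """A fitted standardize-and-SVM pipeline plus its column selection."""

    pipeline: Pipeline
    selected: np.ndarray
    n_features_in: int
    classes: np.ndarray = field(default_factory=lambda: np.array([]))

    def _take(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != self.n_features_in:
            raise ValidationError(
                f"feature layout mismatch: got {features.shape}, model "
                f"expects {self.n_features_in} columns"
            )
        return features[:, self.selected]

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.shape[0] == 0:
            return np.array([], dtype=self.classes.dtype)
        return self.pipeline.predict(self._take(features))

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        """Per-class scores: one-vs-one vote counts + sigmoid margin sums.

        Votes dominate; the squashed sum of pairwise margins breaks vote
        ties, giving a total order usable for ROC construction.
        """
        X = self._take(np.asarray(features, dtype=np.float64))
        svc: SVC = self.pipeline[-1]
        Xs = self.pipeline[:-1].transform(X)
        pairwise = svc.decision_function(Xs)
        if pairwise.ndim == 1:
            pairwise = pairwise[:, None]
        n_classes = len(self.classes)
        votes = np.zeros((X.shape[0], n_classes))
        margins = np.zeros((X.shape[0], n_classes))
        k = 0
        for i in range(n_classes):
            for j in range(i + 1, n_classes):
                d = pairwise[:, k]
                votes[:, i] += d > 0
                votes[:, j] += d <= 0
                margins[:, i] += d
                margins[:, j] -= d
                k += 1
        return votes + 1.0 / (1.0 + np.exp(-margins))

    def save(self, path) -> None:
        joblib.dump(self, Path(path))


@dataclass
class ConceptModel(_SvmModel):
    scale: int = 0


@dataclass
class SceneModel(_SvmModel):
    pass


def _fit_svm(features, labels, selected, kernel: str, C: float,
             seed: int) -> tuple[Pipeline, np.ndarray, int]:
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValidationError("feature matrix must be 2-D and non-empty")
    if features.shape[0] != labels.shape[0]:
        raise ValidationError("labels length does not match feature rows")
    if len(np.unique(labels)) < 2:
        raise ValidationError("training needs at least two classes")
    d = features.shape[1]
    if selected is None:
        selected = np.arange(d)
    selected = np.asarray(selected, dtype=np.intp)
    if selected.size == 0 or selected.min() < 0 or selected.max() >= d:
        raise ValidationError("selected indices out of range")
    if kernel == "poly":
        svc = SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=C,
                  decision_function_shape="ovo", random_state=seed)
    else:
        svc = SVC(kernel="linear", C=C, decision_function_shape="ovo",
                  random_state=seed)
    pipe = Pipeline([("scale", StandardScaler()), ("svm", svc)])
    pipe.fit(features[:, selected], labels)
    return pipe, selected, d


def train_concept_classifier(features, labels, selected=None, scale: int = 0,
                             C: float = 1.0, seed: int = 0) -> ConceptModel:
    """Fit the per-scale patch -> concept SVM (quadratic polynomial kernel)."""
    for lab in np.unique(np.asarray(labels)):
        if lab not in CONCEPT_LABELS:
            raise ValidationError(f"label {lab!r} is not a concept label")
    pipe, sel, d = _fit_svm(features, labels, selected, "poly", C, seed)
    return ConceptModel(pipe, sel, d, classes=pipe.classes_, scale=scale)


def predict_concepts(model: ConceptModel, features) -> np.ndarray:
    """Concept labels (1..5) for a batch of patch feature vectors."""
    features = np.asarray(features, dtype=np.float64)
    if features.size == 0:
        return np.array([], dtype=np.intp)
    return model.predict(features)


def train_scene_classifier(representations, labels, selected=None,
                           C: float = 1.0, seed: int = 0) -> SceneModel:
    """Fit the representation -> severity SVM (linear kernel)."""
    for lab in np.unique(np.asarray(labels)):
        if lab not in SCENE_LABELS:
            raise ValidationError(f"label {lab!r} is not a scene label")
    pipe, sel, d = _fit_svm(representations, labels, selected, "linear", C, seed)
    return SceneModel(pipe, sel, d, classes=pipe.classes_)


def predict_scene(model: SceneModel, representation) -> np.ndarray | str:
    """Severity for one 45-dim representation or a batch of them."""
    rep = np.asarray(representation, dtype=np.float64)
    if rep.ndim == 1:
        if rep.shape[0] != model.n_features_in:
            raise ValidationError(
                f"representation length {rep.shape[0]} does not match model "
                f"({model.n_features_in})"
            )
        return str(model.predict(rep[None, :])[0])
    return model.predict(rep)


def load_model(path):
    """Load a persisted ConceptModel or SceneModel."""
    model = joblib.load(Path(path))
    if not isinstance(model, _SvmModel):
        raise ValidationError(f"{path} does not contain a classifier model")
    return model
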
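"""Confusion-matrix metrics, per-class ROC/AUC and the repeated-split protocol.

With confusion matrix M (rows = true class i, columns = predicted class
j, entries x_ij, marginals x_i+, x_+j, total N):

    acc   = sum_i x_ii / N
    kappa = (N sum_i x_ii - sum_i x_i+ x_+i) / (N^2 - sum_i x_i+ x_+i)
    F1avg = mean_j 2 P_j R_j / (P_j + R_j),  P_j = TP/(TP+FP), R_j = TP/(TP+FN)

computed one-vs-rest per class; a class with no predictions, no true
members, or zero P+R contributes F1 = 0, and a class that is neither
predicted nor true is excluded from the average. AUC uses the rank
(Mann-Whitney) formulation, which equals the trapezoidal area under the
tie-averaged ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .image import ValidationError


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = true class, columns = predicted."""

    counts: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts.ndim != 2
                or self.counts.shape[0] != self.counts.shape[1]):
            raise ValidationError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValidationError("confusion matrix counts must be >= 0")
        if not self.labels:
            self.labels = list(range(self.counts.shape[0]))

    @classmethod
    def from_labels(cls, true, pred, labels=None) -> "ConfusionMatrix":
        true = np.asarray(true).ravel()
        pred = np.asarray(pred).ravel()
        if true.shape != pred.shape:
            raise ValidationError("true/pred length mismatch")
        if labels is None:
            labels = sorted(set(true.tolist()) | set(pred.tolist()))
        index = {lab: k for k, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(true, pred):
            counts[index[t], index[p]] += 1
        return cls(counts, list(labels))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Row-normalized matrix in percent (rows with no samples -> 0)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, self.counts / sums * 100.0, 0.0)
        return pct


def accuracy(m: ConfusionMatrix) -> float:
    """Fraction of samples on the diagonal."""
    n = m.n_total
    if n == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(m.counts) / n)


def cohen_kappa(m: ConfusionMatrix) -> float:
    """Chance-corrected agreement computed from the confusion matrix."""
    n = m.n_total
    if n == 0:
        raise ValidationError("empty confusion matrix")
    chance = float((m.counts.sum(axis=1) * m.counts.sum(axis=0)).sum())
    denom = n * n - chance
    if denom == 0:
        raise ValidationError(
            "kappa undefined: chance agreement equals total agreement"
        )
    return float((n * np.trace(m.counts) - chance) / denom)


def f1_average(m: ConfusionMatrix) -> dict:
    """Per-class one-vs-rest precision/recall/F1 and their macro average.

    Classes that are neither true nor predicted are excluded from the
    average (they carry no evidence either way).
    """
    if m.n_total == 0:
        raise ValidationError("empty confusion matrix")
    tp = np.diag(m.counts).astype(np.float64)
    fp = m.counts.sum(axis=0) - tp
    fn = m.counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    present = (tp + fp + fn) > 0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "f1_avg": float(f1[present].mean()) if present.any() else 0.0,
    }


def roc_auc_per_class(scores: np.ndarray, truth, labels=None) -> dict:
    """One-vs-rest AUC per class from per-class decision values.

    ``scores`` is (n_samples, n_classes) aligned with ``labels``. Ties
    are handled by rank averaging (Mann-Whitney statistic). A class
    absent from the truth, or covering all samples, has no defined AUC
    and maps to None.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).ravel()
    if scores.ndim != 2 or scores.shape[0] != truth.shape[0]:
        raise ValidationError("scores must be (n_samples, n_classes)")
    if labels is None:
        labels = sorted(set(truth.tolist()))
    if scores.shape[1] != len(labels):
        raise ValidationError("score columns do not match class labels")
    out = {}
    for k, lab in enumerate(labels):
        pos = truth == lab
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[lab] = None
            continue
        ranks = rankdata(scores[:, k])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        out[lab] = float(auc)
    return out


@dataclass
class MetricsReport:
    """Aggregate of one evaluation (optionally over repeats)."""

    confusion: ConfusionMatrix
    acc: float
    kappa: float
    f1_avg: float
    per_class: dict
    auc_per_class: dict | None = None

    @classmethod
    def from_predictions(cls, true, pred, labels=None,
                         scores=None) -> "MetricsReport":
        m = ConfusionMatrix.from_labels(true, pred, labels)
        frag = f1_average(m)
        auc = (roc_auc_per_class(scores, true, m.labels)
               if scores is not None else None)
        return cls(m, accuracy(m), cohen_kappa(m), frag["f1_avg"],
                   frag, auc)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.acc,
            "kappa": self.kappa,
            "f1_avg": self.f1_avg,
            "labels": [str(x) for x in self.confusion.labels],
            "confusion_counts": self.confusion.counts.tolist(),
            "confusion_row_pct": self.confusion.row_percentages().tolist(),
            "precision": self.per_class["precision"].tolist(),
            "recall": self.per_class["recall"].tolist(),
            "f1": self.per_class["f1"].tolist(),
        }
        if self.auc_per_class is not None:
            d["auc"] = {str(k): v for k, v in self.auc_per_class.items()}
        return d


def stratified_split(labels: np.ndarray, train_fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random class-stratified train/test index split."""
    labels = np.asarray(labels).ravel()
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    train_idx, test_idx = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            raise ValidationError(
                f"class {lab!r} has {idx.size} sample(s); cannot stratify"
            )
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def repeated_split_evaluation(features: np.ndarray, labels: np.ndarray,
                              fit_predict, n_repeats: int = 20,
                              train_fraction: float = 2.0 / 3.0,
                              seed: int = 0, labels_order=None) -> dict:
    """Repeated stratified hold-out evaluation.

    ``fit_predict(X_train, y_train, X_test, rng)`` must fit a fresh model
    on the training portion only (including any per-repeat feature
    selection) and return predicted labels for the test portion, or a
    ``(predictions, info)`` pair whose ``info`` dict is collected.
    Returns per-repeat metrics plus their means and standard deviations;
    fully reproducible from ``seed``.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    features = np.asarray(features)
    labels = np.asarray(labels).ravel()
    rng = np.random.default_rng(seed)
    if labels_order is None:
        labels_order = sorted(set(labels.tolist()))
    reports, infos = [], []
    for _ in range(n_repeats):
        tr, te = stratified_split(labels, train_fraction, rng)
        result = fit_predict(features[tr], labels[tr], features[te], rng)
        if isinstance(result, tuple):
            pred, info = result
            infos.append(info)
        else:
            pred = result
        reports.append(MetricsReport.from_predictions(
            labels[te], pred, labels=labels_order))
    acc = np.array([r.acc for r in reports])
    kap = np.array([r.kappa for r in reports])
    f1 = np.array([r.f1_avg for r in reports])
    pooled = ConfusionMatrix(
        np.sum([r.confusion.counts for r in reports], axis=0), labels_order)
    return {
        "reports": reports,
        "infos": infos,
        "accuracy_mean": float(acc.mean()), "accuracy_std": float(acc.std()),
        "kappa_mean": float(kap.mean()), "kappa_std": float(kap.std()),
        "f1_mean": float(f1.mean()), "f1_std": float(f1.std()),
        "pooled_confusion": pooled,
    }
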
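"""Fuzzy-information feature selection with greedy forward search.

Each real-valued feature is fuzzified into three triangular sets
(low/mid/high) anchored at the minimum, midpoint and maximum of its
training values; the three membership degrees of any value sum to 1.
Set probabilities are then estimated as (normalized) mean memberships,
joint memberships via the minimum t-norm, and Shannon entropies of those
probabilities provide marginal, joint and conditional entropies and
(conditional) mutual information. On crisp 0/1 memberships the whole
construction reduces exactly to the discrete plug-in estimators. The
Luca-Termini measure of fuzziness is exposed separately and used to flag
degenerate (constant) features.

A candidate feature f is scored against the selected set S and the class
C by a high-order dependency criterion::

    J(f) = I(f;C) - (1/|S|) sum_s I(f;s) + (1/|S|) sum_s I(f;s|C)
           + beta * (2/(|S|(|S|-1))) * sum_{s<s'} [I(f;(s,s')|C) - I(f;(s,s'))]

i.e. relevance, minus unconditional redundancy, plus class-conditional
redundancy, plus a second-order interaction term (active once two
features are selected, weight beta = 0.5). Forward search greedily adds
the argmax-J candidate, breaking ties toward the lowest feature index,
and stops at ``k_max`` features or when the best score drops to <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import ValidationError

N_FUZZY_SETS = 3
DEFAULT_BETA = 0.5
_LOG2 = np.log(2.0)


# --------------------------------------------------------------------------
# fuzzification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FuzzyAnchors:
    """Min / midpoint / max anchors of one feature's triangular partition."""

    lo: float
    mid: float
    hi: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "FuzzyAnchors":
        lo, hi = float(np.min(values)), float(np.max(values))
        return cls(lo, (lo + hi) / 2.0, hi)

    @property
    def degenerate(self) -> bool:
        return not self.hi > self.lo


def fuzzify(values: np.ndarray, anchors: FuzzyAnchors | None = None) -> np.ndarray:
    """Triangular low/mid/high membership degrees, one row per sample.

    Rows sum to 1 (partition of unity). Values outside [lo, hi] clamp to
    the nearest anchor. A degenerate feature (max == min) puts all mass
    on the mid set.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if anchors is None:
        anchors = FuzzyAnchors.from_values(values)
    m = np.zeros((values.size, N_FUZZY_SETS))
    if anchors.degenerate:
        m[:, 1] = 1.0
        return m
    v = np.clip(values, anchors.lo, anchors.hi)
    left = v <= anchors.mid
    t = np.empty_like(v)
    t[left] = (v[left] - anchors.lo) / (anchors.mid - anchors.lo)
    t[~left] = (v[~left] - anchors.mid) / (anchors.hi - anchors.mid)
    m[left, 0] = 1.0 - t[left]
    m[left, 1] = t[left]
    m[~left, 1] = 1.0 - t[~left]
    m[~left, 2] = t[~left]
    return m


def crisp_memberships(labels: np.ndarray) -> np.ndarray:
    """One-hot (crisp) membership matrix of a categorical variable."""
    labels = np.asarray(labels).ravel()
    cats = np.unique(labels)
    return (labels[:, None] == cats[None, :]).astype(np.float64)


def luca_termini_entropy(memberships: np.ndarray, n: int | None = None) -> float:
    """Luca-Termini fuzziness of a membership assignment, in bits.

    ``H = -(1/n) sum_i [mu_i log2 mu_i + (1 - mu_i) log2(1 - mu_i)]``
    with 0 log 0 = 0; for a multi-set variable the contributions of all
    fuzzy sets are summed. Crisp (0/1) memberships have zero fuzziness;
    a single degree of 0.5 contributes one bit.
    """
    mu = np.asarray(memberships, dtype=np.float64)
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValidationError("membership degrees must lie in [0, 1]")
    if n is None:
        n = mu.shape[0] if mu.ndim > 0 and mu.size else 1
    with np.errstate(divide="ignore", invalid="ignore"):
        term = mu * np.log2(mu) + (1.0 - mu) * np.log2(1.0 - mu)
    term = np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0)
    return float(-term.sum() / n)


# --------------------------------------------------------------------------
# information measures on fuzzified variables
# --------------------------------------------------------------------------

def _check_same_n(*vars_: np.ndarray) -> int:
    ns = {v.shape[0] for v in vars_}
    if len(ns) != 1:
        raise ValidationError(f"sample-count mismatch between variables: {ns}")
    return ns.pop()


def _shannon(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=np.float64).ravel()
    total = p.sum()
    if total <= 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def joint_memberships(*vars_: np.ndarray) -> np.ndarray:
    """Minimum t-norm joint membership over the Cartesian set product.

    Input: membership matrices of shape (n, k_i). Output: (n, prod k_i).
    """
    n = _check_same_n(*vars_)
    out = vars_[0]
    for v in vars_[1:]:
        out = np.minimum(out[:, :, None], v[:, None, :]).reshape(n, -1)
    return out


def entropy(*vars_: np.ndarray) -> float:
    """(Joint) entropy in bits of one or more fuzzified variables."""
    return _shannon(joint_memberships(*vars_).mean(axis=0))


def joint_entropy(x: np.ndarray, y: np.ndarray) -> float:
    return entropy(x, y)


def conditional_entropy(x: np.ndarray, y: np.ndarray) -> float:
    """H(X | Y) = H(X, Y) - H(Y)."""
    return entropy(x, y) - entropy(y)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """I(X; Y) = H(X) + H(Y) - H(X, Y)."""
    return entropy(x) + entropy(y) - entropy(x, y)


def conditional_mutual_information(x: np.ndarray, y: np.ndarray,
                                   z: np.ndarray) -> float:
    """I(X; Y | Z) = H(X, Z) + H(Y, Z) - H(X, Y, Z) - H(Z)."""
    return entropy(x, z) + entropy(y, z) - entropy(x, y, z) - entropy(z)


# --------------------------------------------------------------------------
# candidate scoring and forward search
# --------------------------------------------------------------------------

def score_candidate(f: int, selected: list[int], fuzzified: list[np.ndarray],
                    class_m: np.ndarray, beta: float = DEFAULT_BETA) -> float:
    """High-order dependency score of candidate feature ``f`` given S and C."""
    if f in selected:
        raise ValidationError(f"candidate {f} already selected")
    fm = fuzzified[f]
    j = mutual_information(fm, class_m)
    if not selected:
        return j
    k = len(selected)
    red = sum(mutual_information(fm, fuzzified[s]) for s in selected)
    cred = sum(
        conditional_mutual_information(fm, fuzzified[s], class_m)
        for s in selected
    )
    j += (cred - red) / k
    if k >= 2:
        inter = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                pair = joint_memberships(fuzzified[selected[a]],
                                         fuzzified[selected[b]])
                inter += (conditional_mutual_information(fm, pair, class_m)
                          - mutual_information(fm, pair))
        j += beta * 2.0 / (k * (k - 1)) * inter
    return j


@dataclass
class SelectionState:
    """Result of a forward search: ordered indices, scores, anchors."""

    selected: list[int] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    anchors: list[FuzzyAnchors] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected": list(map(int, self.selected)),
            "scores": list(map(float, self.scores)),
            "anchors": [[a.lo, a.mid, a.hi] for a in self.anchors],
        }


class _SearchCache:
    """Vectorized, memoized entropy terms for one forward search.

    Candidate-wise quantities are computed for all remaining candidates
    at once by broadcasting candidate membership tensors against the
    (cached) joint memberships of selected features/pairs.
    """

    def __init__(self, fuzzified: np.ndarray, class_m: np.ndarray,
                 beta: float):
        self.M = fuzzified              # (F, n, 3)
        self.C = class_m                # (n, nc)
        self.beta = beta
        self.n = class_m.shape[0]
        self.F = fuzzified.shape[0]
        self.h_c = _shannon(class_m.mean(axis=0))
        self.h_f = np.array([_shannon(m.mean(axis=0)) for m in fuzzified])
        # H(f, C) for all f at once
        fc = np.minimum(fuzzified[:, :, :, None], class_m[None, :, None, :])
        self.h_fc = self._h_batch(fc.reshape(self.F, self.n, -1))
        self.rel = self.h_f + self.h_c - self.h_fc  # I(f;C)
        self.red_sum = np.zeros(self.F)    # sum_s I(f;s)
        self.cred_sum = np.zeros(self.F)   # sum_s I(f;s|C)
        self.inter_sum = np.zeros(self.F)  # sum_{s<s'} [I(f;ss'|C)-I(f;ss')]
        self.selected: list[int] = []

    @staticmethod
    def _h_batch(joint: np.ndarray) -> np.ndarray:
        """Shannon entropies of normalized mean memberships, batched."""
        p = joint.mean(axis=1)
        p = p / np.maximum(p.sum(axis=1, keepdims=True), 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = p * np.log2(p)
        return -np.nan_to_num(t, nan=0.0).sum(axis=1)

    def _joint_with_candidates(self, base: np.ndarray) -> np.ndarray:
        """(F,) entropies H(f, base) for a fixed joint membership ``base``."""
        j = np.minimum(self.M[:, :, :, None], base[None, :, None, :])
        return self._h_batch(j.reshape(self.F, self.n, -1))

    def add(self, s: int) -> None:
        """Update cached per-candidate sums after selecting feature ``s``."""
        sm = self.M[s]                       # (n, 3)
        sc = joint_memberships(sm, self.C)   # (n, 3*nc)
        h_s = _shannon(sm.mean(axis=0))
        h_sc = _shannon(sc.mean(axis=0))
        h_fs = self._joint_with_candidates(sm)
        h_fsc = self._joint_with_candidates(sc)
        # I(f;s) = H(f)+H(s)-H(f,s);  I(f;s|C) = H(f,C)+H(s,C)-H(f,s,C)-H(C)
        self.red_sum += self.h_f + h_s - h_fs
        self.cred_sum += self.h_fc + h_sc - h_fsc - self.h_c
        # new pairs (s, s') for all previously selected s'
        for sp in self.selected:
            pair = joint_memberships(sm, self.M[sp])       # (n, 9)
            pair_c = joint_memberships(pair, self.C)       # (n, 9*nc)
            h_p = _shannon(pair.mean(axis=0))
            h_pc = _shannon(pair_c.mean(axis=0))
            h_fp = self._joint_with_candidates(pair)
            h_fpc = self._joint_with_candidates(pair_c)
            i_pair = self.h_f + h_p - h_fp
            i_pair_c = self.h_fc + h_pc - h_fpc - self.h_c
            self.inter_sum += i_pair_c - i_pair
        self.selected.append(s)

    def scores(self) -> np.ndarray:
        """Current J(f) for every feature (selected ones set to -inf)."""
        k = len(self.selected)
        j = self.rel.copy()
        if k >= 1:
            j += (self.cred_sum - self.red_sum) / k
        if k >= 2:
            j += self.beta * 2.0 / (k * (k - 1)) * self.inter_sum
        j[self.selected] = -np.inf
        return j


def forward_select(features: np.ndarray, labels: np.ndarray,
                   k_max: int | None = None,
                   beta: float = DEFAULT_BETA) -> SelectionState:
    """Greedy forward search maximizing the high-order dependency score.

    Deterministic: the argmax candidate is added each step (ties to the
    lowest index); the search stops at ``k_max`` features or when the
    best score is <= 0.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.size == 0:
        raise ValidationError("feature matrix must be 2-D and non-empty")
    n, d = features.shape
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != n:
        raise ValidationError("labels length does not match feature rows")
    if k_max is None:
        k_max = d
    if k_max > d:
        raise ValidationError(f"k_max {k_max} exceeds feature count {d}")

    anchors = [FuzzyAnchors.from_values(features[:, i]) for i in range(d)]
    fuzzified = np.stack(
        [fuzzify(features[:, i], anchors[i]) for i in range(d)]
    )
    class_m = crisp_memberships(labels)

    cache = _SearchCache(fuzzified, class_m, beta)
    state = SelectionState(anchors=anchors)
    for _ in range(k_max):
        scores = cache.scores()
        best = int(np.argmax(scores))  # argmax takes the first (lowest) index
        if not scores[best] > 0:
            break
        cache.add(best)
        state.selected.append(best)
        state.scores.append(float(scores[best]))
    return state
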
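"""ROI multivoxel decoding: pairwise linear SVMs with one-vs-one voting.

Four-way category decoding is performed with the six pairwise linear
max-margin classifiers (cost parameter C = 1), a majority vote over pairwise
winners, and a summed-decision-value tie-break.  Cross-validation leaves one
acquisition run out per fold; per-category accuracies are pooled over folds
(summing correct/total counts) and averaged to a balanced accuracy, so the
result is robust to category imbalance in the test sets.

Decision-value orientation: within each unordered pair the decision value is
signed positive toward the index-first category (category order as supplied,
default alphabetical), and a candidate's summed score flips the sign of every
pairwise value accordingly.  Exact multi-way ties fall back to the lowest
category index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.svm import SVC


@dataclass
class PairwiseModel:
    """C(k,2) binary linear models, one per unordered category pair."""

    categories: tuple[str, ...]
    weights: dict[tuple[str, str], np.ndarray]
    offsets: dict[tuple[str, str], float]

    def decision_values(self, X: np.ndarray) -> dict[tuple[str, str], np.ndarray]:
        """Signed decision value per pair, positive toward the pair's first category."""
        X = np.atleast_2d(X)
        return {
            pair: X @ self.weights[pair] + self.offsets[pair]
            for pair in self.weights
        }


def train_pairwise(
    X: np.ndarray, y: np.ndarray, *, categories: tuple[str, ...] | None = None, C: float = 1.0
) -> PairwiseModel:
    """Fit one linear SVM (cost C) per category pair.

    Raises if any category has no training sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if categories is None:
        categories = tuple(sorted(np.unique(y)))
    missing = [c for c in categories if not np.any(y == c)]
    if missing:
        raise ValueError(f"categories absent from training set: {missing}")
    weights: dict[tuple[str, str], np.ndarray] = {}
    offsets: dict[tuple[str, str], float] = {}
    for a, b in combinations(categories, 2):
        m = (y == a) | (y == b)
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[m], y[m])
        w = clf.coef_.ravel().copy()
        b0 = float(clf.intercept_[0])
        # sklearn orients the decision value toward clf.classes_[1];
        # re-orient toward the index-first category `a`.
        if clf.classes_[1] != a:
            w, b0 = -w, -b0
        weights[(a, b)] = w
        offsets[(a, b)] = b0
    return PairwiseModel(tuple(categories), weights, offsets)


def predict_multiclass(model: PairwiseModel, X: np.ndarray) -> np.ndarray:
    """One-vs-one vote; ties resolved by maximal summed signed decision value,
    then by lowest category index."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cats = model.categories
    n = X.shape[0]
    votes = np.zeros((n, len(cats)))
    sums = np.zeros((n, len(cats)))
    dv = model.decision_values(X)
    idx = {c: i for i, c in enumerate(cats)}
    for (a, b), d in dv.items():
        winner_a = d > 0
        votes[:, idx[a]] += winner_a
        votes[:, idx[b]] += ~winner_a
        sums[:, idx[a]] += d
        sums[:, idx[b]] -= d
    pred = np.empty(n, dtype=object)
    for i in range(n):
        top = votes[i].max()
        tied = np.flatnonzero(votes[i] == top)
        if len(tied) > 1:
            best = sums[i, tied].max()
            tied = tied[sums[i, tied] == best]
        pred[i] = cats[tied[0]]
    return pred


@dataclass
class DecodingResult:
    balanced_accuracy: float
    per_category: dict[str, float]
    counts: dict[str, tuple[int, int]]  # category -> (correct, total)
    n_folds: int
    skipped_folds: list[int] = field(default_factory=list)


def leave_one_run_out(runs: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Fold scheme: (train mask, test mask, held-out run) per unique run."""
    runs = np.asarray(runs)
    return [(runs != r, runs == r, r) for r in np.unique(runs)]


def _predict_nearest_centroid(Xtr, ytr, Xte, categories):
    mus = np.stack([Xtr[ytr == c].mean(axis=0) for c in categories])
    d2 = ((Xte[:, None, :] - mus[None]) ** 2).sum(axis=2)
    return np.array([categories[i] for i in np.argmin(d2, axis=1)], dtype=object)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    runs: np.ndarray,
    *,
    categories: tuple[str, ...] | None = None,
    C: float = 1.0,
    decoder: str = "svm",
) -> DecodingResult:
    """Leave-one-run-out decoding with pooled per-category accuracy.

    ``decoder`` is "svm" (the pairwise max-margin decoder with one-vs-one
    voting) or "nearest_centroid" (a fast Euclidean nearest-class-mean
    classifier, useful for large permutation calibration studies where the
    classifier identity is immaterial).  Folds whose training split lacks a
    category are skipped and recorded; a category absent from every training
    split raises.
    """
    if decoder not in ("svm", "nearest_centroid"):
        raise ValueError(f"unknown decoder {decoder!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    runs = np.asarray(runs)
    if categories is None:
        categories = tuple(sorted(np.unique(y)))
    folds = leave_one_run_out(runs)
    if len(folds) < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    correct = {c: 0 for c in categories}
    total = {c: 0 for c in categories}
    skipped: list[int] = []
    trainable = {c: False for c in categories}
    for train, test, run in folds:
        ytr = y[train]
        missing = [c for c in categories if not np.any(ytr == c)]
        for c in categories:
            if np.any(ytr == c):
                trainable[c] = True
        if missing:
            skipped.append(int(run))
            continue
        if decoder == "svm":
            model = train_pairwise(X[train], ytr, categories=categories, C=C)
            pred = predict_multiclass(model, X[test])
        else:
            pred = _predict_nearest_centroid(X[train], ytr, X[test], categories)
        for yt, yp in zip(y[test], pred):
            total[yt] += 1
            correct[yt] += yt == yp
    never = [c for c in categories if not trainable[c]]
    if never:
        raise ValueError(f"categories absent from every training split: {never}")
    if all(t == 0 for t in total.values()):
        raise ValueError("no testable folds (all folds skipped)")
    per_cat = {c: correct[c] / total[c] for c in categories if total[c] > 0}
    bal = float(np.mean(list(per_cat.values())))
    counts = {c: (correct[c], total[c]) for c in categories}
    return DecodingResult(bal, per_cat, counts, len(folds) - len(skipped), skipped)


def match_voxel_counts(
    mask_a: np.ndarray, mask_b: np.ndarray, selection_stat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize two ROI voxel counts by trimming the larger ROI.

    The removed voxels are exactly those with the lowest ``selection_stat``
    (e.g. a localizer parameter estimate) within the larger ROI; ties at the
    cut boundary are broken by voxel index order (lower index dropped first).
    Masks may be boolean arrays of any matching shape.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    stat = np.asarray(selection_stat, dtype=float)
    if a.shape != b.shape or a.shape != stat.shape:
        raise ValueError("masks and selection_stat must share a shape")
    na, nb = int(a.sum()), int(b.sum())
    if na == nb:
        return a.copy(), b.copy()
    big, n_keep = (a, nb) if na > nb else (b, na)
    flat_idx = np.flatnonzero(big.ravel())
    order = np.lexsort((flat_idx, stat.ravel()[flat_idx]))  # ascending stat, then index
    drop = flat_idx[order[: len(flat_idx) - n_keep]]
    trimmed = big.copy().ravel()
    trimmed[drop] = False
    trimmed = trimmed.reshape(big.shape)
    return (trimmed, b.copy()) if na > nb else (a.copy(), trimmed)
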
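"""Sequential forward floating selection (SFFS) of at most five features.

Classic SFFS: each forward step adds the candidate feature whose inclusion
maximizes the criterion; after every addition, conditional backward steps
remove a feature as long as the removal strictly improves the best score
recorded so far at the resulting subset size.  The search stops once the
working set has reached ``max_features`` and no exclusion helps.  The
returned selection is the best-scoring subset found at any size (ties break
toward the smaller subset, then lexicographic column order); the cap of
five mirrors the small-cohort setting where larger SVM inputs overfit.

The default criterion is the wrapper the downstream classifier implies:
mean accuracy of a linear SVM under an internal stratified 5-fold
cross-validation of the training rows.  Tie-breaking between candidate
features is by lowest column index, so the whole procedure is deterministic
given the seed and input column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .types import DegenerateLabelsError, InvalidArgumentError

__all__ = ["SelectionTrace", "sffs", "svm_cv_criterion"]

Criterion = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class SelectionTrace:
    """Audit trail of an SFFS run.

    ``steps`` records every accepted action as (action, feature name,
    criterion value of the resulting subset); ``selected`` is the final
    feature-name list (1..max_features names) and ``score`` its criterion.
    """

    steps: list[tuple[str, str, float]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    score: float = float("-inf")


def svm_cv_criterion(seed: int, n_splits: int = 5) -> Criterion:
    """Mean accuracy of a linear SVM under internal stratified k-fold CV."""

    def criterion(X: np.ndarray, y: np.ndarray) -> float:
        classes, counts = np.unique(y, return_counts=True)
        splits = min(n_splits, int(counts.min()))
        if splits < 2:
            raise DegenerateLabelsError("criterion needs >= 2 members per class")
        cv = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
        correct = 0
        for train_idx, test_idx in cv.split(X, y):
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(X[train_idx], y[train_idx])
            correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
        return correct / len(y)

    return criterion


def sffs(
    features: "np.ndarray | object",
    labels: Sequence,
    max_features: int = 5,
    criterion: Criterion | None = None,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> SelectionTrace:
    """Run SFFS on a (rows x columns) feature array.

    Parameters
    ----------
    features : array or DataFrame
        Training rows only; a DataFrame supplies ``feature_names``.
    labels : class vector with exactly two classes present.
    max_features : maximum subset size (default 5).
    criterion : subset score; default is :func:`svm_cv_criterion` at `seed`.
    seed : drives the internal cross-validation split of the default
        criterion; the search itself is deterministic.
    """
    if hasattr(features, "columns"):
        feature_names = [str(c) for c in features.columns]  # type: ignore[union-attr]
        X = features.to_numpy(dtype=float)  # type: ignore[union-attr]
    else:
        X = np.asarray(features, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if max_features < 1:
        raise InvalidArgumentError("max_features must be >= 1")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("sffs requires both classes in the labels")
    if criterion is None:
        criterion = svm_cv_criterion(seed)

    n_features = X.shape[1]
    cache: dict[frozenset[int], float] = {}

    def score(subset: frozenset[int]) -> float:
        if subset not in cache:
            cols = sorted(subset)
            cache[subset] = float(criterion(X[:, cols], y))
        return cache[subset]

    trace = SelectionTrace()
    best_at_size: dict[int, tuple[float, frozenset[int]]] = {}
    current: frozenset[int] = frozenset()

    def record_best(subset: frozenset[int], value: float) -> None:
        size = len(subset)
        if size == 0:
            return
        prev = best_at_size.get(size)
        if prev is None or value > prev[0] or (
            value == prev[0] and sorted(subset) < sorted(prev[1])
        ):
            best_at_size[size] = (value, subset)

    while len(current) < max_features:
        # Forward step: add the best candidate (ties -> lowest column index).
        best_j, best_val = -1, float("-inf")
        for j in range(n_features):
            if j in current:
                continue
            val = score(current | {j})
            if val > best_val:
                best_j, best_val = j, val
        if best_j < 0:
            break
        current = current | {best_j}
        record_best(current, best_val)
        trace.steps.append(("add", feature_names[best_j], best_val))

        # Conditional backward steps: remove while removal strictly improves
        # the best score recorded at the smaller size.
        while len(current) > 2:
            best_rm, best_rm_val = -1, float("-inf")
            for j in sorted(current):
                val = score(current - {j})
                if val > best_rm_val:
                    best_rm, best_rm_val = j, val
            smaller = len(current) - 1
            prev = best_at_size.get(smaller)
            if prev is not None and best_rm_val > prev[0]:
                current = current - {best_rm}
                record_best(current, best_rm_val)
                trace.steps.append(("remove", feature_names[best_rm], best_rm_val))
            else:
                break

    # Final selection: best subset over all sizes 1..max_features
    # (ties -> smaller size, then lexicographic column order).
    best_size = None
    for size, (value, subset) in sorted(best_at_size.items()):
        if best_size is None or value > trace.score:
            trace.score = value
            best_size = size
            trace.selected = [feature_names[j] for j in sorted(subset)]
    return trace
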
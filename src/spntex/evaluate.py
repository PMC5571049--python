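"""Cross-validated SVM models, pooled ROC evaluation and DeLong comparison.

Five feature-set models are built from the 177-column cohort matrix (eCT,
ePET, ePET/CT, dPET, edPET/CT).  For each outer fold of a stratified 5-fold
split, features are standardized on the training rows, SFFS selects at most
five features, a linear SVM (C = 1) is fit, and the held-out rows are scored
with the margin decision value.  Out-of-fold scores from all folds are
pooled into ONE ROC per model (the mean of per-fold AUCs is also reported),
and models are compared with DeLong's structural-components test for paired
AUCs.  The optimal operating point is the one nearest the upper-left corner
of the ROC plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import SelectionTrace, sffs, svm_cv_criterion
from .types import (
    DegenerateLabelsError,
    DegenerateVarianceError,
    InvalidArgumentError,
    StratificationError,
)

__all__ = [
    "FeatureSetSpec",
    "FEATURE_SETS",
    "CVResult",
    "ROCCurve",
    "ConfusionCounts",
    "stratified_kfold",
    "cross_validate_model",
    "roc_auc",
    "delong_test",
    "optimal_threshold",
    "confusion_metrics",
    "confusion_at_threshold",
    "selection_frequency",
    "POSITIVE_LABEL",
]

POSITIVE_LABEL = "malignant"


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named model input: which column prefixes of the 177 enter."""

    name: str
    prefixes: tuple[str, ...]

    def columns(self, matrix: pd.DataFrame) -> list[str]:
        cols = [
            c for c in matrix.columns
            if any(c.startswith(p + "_") for p in self.prefixes)
        ]
        if not cols:
            raise InvalidArgumentError(
                f"feature set {self.name!r}: no columns with prefixes {self.prefixes}"
            )
        return cols


FEATURE_SETS: dict[str, FeatureSetSpec] = {
    "eCT": FeatureSetSpec("eCT", ("CT",)),
    "ePET": FeatureSetSpec("ePET", ("ePET",)),
    "ePET/CT": FeatureSetSpec("ePET/CT", ("ePET", "CT")),
    "dPET": FeatureSetSpec("dPET", ("dPET",)),
    "edPET/CT": FeatureSetSpec("edPET/CT", ("ePET", "CT", "dPET")),
}


@dataclass
class CVResult:
    """Pooled out-of-fold scores and per-fold selections for one model."""

    model: str
    fold_assignment: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    fold_selections: list[list[str]]
    fold_traces: list[SelectionTrace]
    fold_aucs: list[float]

    @property
    def pooled_auc(self) -> float:
        return roc_auc(self.scores, self.labels).auc

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


@dataclass
class ROCCurve:
    """Empirical ROC: operating points sorted by threshold, plus AUC.

    Each operating point is the rule ``score >= threshold -> malignant``;
    ``tp``/``fp`` carry the raw counts behind the rates so confusion counts
    at any point are exact.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    n_pos: int
    n_neg: int
    auc: float


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return _ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.tn, self.tn + self.fn)


def _ratio(num: int, den: int) -> float:
    # Zero denominators are undefined; returned as nan so downstream
    # reporting can flag them instead of inventing a rate.
    return num / den if den else float("nan")


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionCounts:
    """Derived proportions from confusion counts (nan where undefined)."""
    if min(tp, fp, tn, fn) < 0:
        raise InvalidArgumentError("counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise InvalidArgumentError("confusion_metrics requires at least one count")
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _binary_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray([1 if l == POSITIVE_LABEL else 0 for l in labels])
    if y.min() == y.max():
        raise DegenerateLabelsError("both classes must be present")
    return y


def stratified_kfold(labels: Sequence, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1 per lesion), stratified and seed-deterministic."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(cv.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def cross_validate_model(
    matrix: pd.DataFrame,
    labels: Sequence,
    spec: FeatureSetSpec,
    k: int = 5,
    seed: int = 0,
    max_features: int = 5,
    fold_assignment: Optional[np.ndarray] = None,
) -> CVResult:
    """Cross-validate one feature-set model; every lesion scored exactly once.

    Per fold: standardize on training rows, SFFS on the spec's columns, fit
    a linear SVM (C = 1) on the selected features, score validation rows
    with the margin decision value.
    """
    y = _binary_labels(labels)
    cols = spec.columns(matrix)
    X = matrix[cols].to_numpy(dtype=float)
    if fold_assignment is None:
        fold_assignment = stratified_kfold(labels, k=k, seed=seed)

    scores = np.full(len(y), np.nan)
    fold_selections: list[list[str]] = []
    fold_traces: list[SelectionTrace] = []
    fold_aucs: list[float] = []
    for fold in range(k):
        test = fold_assignment == fold
        train = ~test
        scaler = StandardScaler().fit(X[train])
        Xtr = scaler.transform(X[train])
        Xte = scaler.transform(X[test])
        trace = sffs(
            Xtr,
            y[train],
            max_features=max_features,
            criterion=svm_cv_criterion(seed + fold),
            feature_names=cols,
        )
        sel_idx = [cols.index(name) for name in trace.selected]
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Xtr[:, sel_idx], y[train])
        scores[test] = clf.decision_function(Xte[:, sel_idx])
        fold_selections.append(list(trace.selected))
        fold_traces.append(trace)
        if len(np.unique(y[test])) == 2:
            fold_aucs.append(roc_auc(scores[test], np.asarray(labels)[test]).auc)
    assert not np.isnan(scores).any(), "every lesion must receive one pooled score"
    return CVResult(
        model=spec.name,
        fold_assignment=fold_assignment,
        scores=scores,
        labels=np.asarray(labels),
        fold_selections=fold_selections,
        fold_traces=fold_traces,
        fold_aucs=fold_aucs,
    )


def roc_auc(scores: Sequence[float], labels: Sequence) -> ROCCurve:
    """Empirical ROC over all score thresholds; AUC by the rank-sum (
    Mann-Whitney) probability with tie correction."""
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos

    # One operating point per distinct threshold value (score >= t -> positive),
    # plus the trivial all-negative point at threshold +inf.
    last = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.r_[0, np.cumsum(y_sorted)[last]]
    fp = np.r_[0, np.cumsum(1 - y_sorted)[last]]
    thresholds = np.r_[np.inf, s_sorted[last]]

    # Tie-corrected rank-sum AUC.
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    asc = slice(None, None, -1)  # points sorted by ascending threshold
    return ROCCurve(
        thresholds=thresholds[asc],
        sensitivity=(tp / n_pos)[asc],
        specificity=(1.0 - fp / n_neg)[asc],
        tp=tp[asc].astype(int),
        fp=fp[asc].astype(int),
        n_pos=n_pos,
        n_neg=n_neg,
        auc=float(auc),
    )


def _structural_components(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(x, y) = 1 if x > y, 0.5 if tied, else 0
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    return v10, v01, float(psi.mean())


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated AUCs on the same lesions.

    Returns ``(auc_a, auc_b, z, two_sided_p)``.  The variance of the AUC
    difference is estimated from the structural components V10 (per positive
    case) and V01 (per negative case) of both score vectors.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise InvalidArgumentError("paired score vectors must have equal length")
    y = _binary_labels(labels)
    v10_a, v01_a, auc_a = _structural_components(sa, y)
    v10_b, v01_b, auc_b = _structural_components(sb, y)
    m = len(v10_a)
    n = len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        if delta == 0:
            return auc_a, auc_b, 0.0, 1.0
        raise DegenerateVarianceError(
            "zero variance of the AUC difference with a nonzero difference"
        )
    z = delta / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return auc_a, auc_b, float(z), min(p, 1.0)


def optimal_threshold(roc: ROCCurve) -> tuple[float, ConfusionCounts]:
    """Operating point nearest the (0, 1) corner of the ROC plot.

    Minimizes sqrt((1-sens)^2 + (1-spec)^2); ties break toward higher
    sensitivity.  Returns the threshold and the confusion counts implied by
    the curve's sample sizes at that point.
    """
    dist = np.hypot(1.0 - roc.sensitivity, 1.0 - roc.specificity)
    best = np.lexsort((-roc.sensitivity, dist))[0]
    tp = int(roc.tp[best])
    fp = int(roc.fp[best])
    counts = ConfusionCounts(
        tp=tp, fp=fp, tn=roc.n_neg - fp, fn=roc.n_pos - tp
    )
    return float(roc.thresholds[best]), counts


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence, threshold: float
) -> ConfusionCounts:
    """Confusion counts for the rule score >= threshold -> malignant."""
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def selection_frequency(cv_results: Iterable[CVResult]) -> pd.DataFrame:
    """Per (model, feature) count of folds selecting the feature.

    The per-model maximum equals the number of folds; for combined models
    the image-type prefix of each feature name keeps early and delayed PET
    counts separate.  Features never selected are absent.
    """
    rows = []
    results = list(cv_results)
    if not results:
        raise InvalidArgumentError("selection_frequency requires >= 1 CV result")
    for res in results:
        counts: dict[str, int] = {}
        for sel in res.fold_selections:
            for name in sel:
                counts[name] = counts.get(name, 0) + 1
        for name, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append({"model": res.model, "feature": name, "count": count})
    return pd.DataFrame(rows, columns=["model", "feature", "count"])
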
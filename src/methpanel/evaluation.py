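"""Model-assessment machinery: ROC/AUC, binary metrics, folds, bootstrap.

AUC is computed from the Mann-Whitney rank statistic with tie correction
(exact, including tied scores); the ROC curve itself is kept for export and
equals the trapezoidal integral of the stored points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .datatypes import ValidationError


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # TPR, one per curve point
    fpr: np.ndarray  # 1 - specificity
    auc: float


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-corrected rank probability P(score+ > score-)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes required for AUC")
    ranks = rankdata(scores)  # average ranks handle ties exactly
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve over sorted unique thresholds plus the rank-statistic AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    auc = rank_auc(scores, labels)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # keep the last point of each tied-score block
    last_of_block = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp, fp = tp[last_of_block], fp[last_of_block]
    thresholds = sorted_scores[last_of_block]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, thresholds]
    return RocResult(thresholds=thresholds, sensitivity=tpr, fpr=fpr, auc=auc)


def binary_metrics(scores, labels, cutoff: float = 0.5) -> dict[str, float]:
    """2x2 confusion metrics; predicted positive iff score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValidationError("both classes required for binary metrics")
    pred = scores >= cutoff
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(labels)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "misclassification": 1.0 - acc,
    }


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Class-balanced fold assignment (0..k-1), deterministic under seed.

    ``k`` is reduced (with a warning) to the smallest class size when a
    class has fewer than ``k`` members; a singleton class is an error.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise ValidationError("a class with a single member cannot be folded")
    if min_count < k:
        warnings.warn(f"reducing fold count from {k} to {min_count} "
                      "(smallest class size)", stacklevel=2)
        k = min_count
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def stratified_bootstrap_indices(
    labels, rng: np.random.Generator
) -> np.ndarray:
    """One bootstrap resample drawn with replacement within each class."""
    labels = np.asarray(labels)
    out = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        out.append(rng.choice(idx, size=len(idx), replace=True))
    return np.sort(np.concatenate(out))


def youden_cutoff(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1."""
    roc = roc_auc(scores, labels)
    j = roc.sensitivity - roc.fpr
    best = int(np.argmax(j))
    thr = roc.thresholds[best]
    return float(thr if np.isfinite(thr) else np.max(scores) + 1.0)
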
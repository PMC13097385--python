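"""Cross-validated evaluation: accuracy, ROC-AUC, confusion, t-SNE.

Fold splitting is at the *subject* level (all of a subject's trial
windows travel together), stratified by group label, which avoids the
leakage a window-level split would cause.  Per-subject scores are the
mean predicted sarcopenia probability across the subject's windows, and
accuracy / confusion counts are reported per subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .model import (
    Dataset,
    FusionModelConfig,
    predict_proba,
    train,
    train_baseline,
)

__all__ = ["CVReport", "kfold_cv", "roc_auc", "tsne_embed"]


@dataclass
class CVReport:
    fold_assignments: dict[str, int]
    per_fold_accuracy: list[float]
    mean_accuracy: float
    confusion_matrix: list[list[int]]  # rows = true class, cols = predicted
    roc_points: list[tuple[float, float]]
    auc: float
    subject_scores: dict[str, float] = field(default_factory=dict)
    subject_labels: dict[str, int] = field(default_factory=dict)

    def confusion_row_normalized(self) -> np.ndarray:
        cm = np.asarray(self.confusion_matrix, dtype=float)
        return cm / np.maximum(cm.sum(axis=1, keepdims=True), 1)

    def confusion_global_proportions(self) -> np.ndarray:
        cm = np.asarray(self.confusion_matrix, dtype=float)
        return cm / max(cm.sum(), 1)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """Empirical ROC curve and its trapezoidal AUC.

    Equals the Mann–Whitney U statistic divided by n_pos * n_neg (tied
    scores receive half concordance credit).  Raises if only one class is
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC requires both classes present")

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # keep only the last index of each tied-score run
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def kfold_cv(
    dataset: Dataset,
    model_spec: FusionModelConfig | str,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Subject-level stratified k-fold cross-validation.

    ``model_spec`` is either a :class:`FusionModelConfig` (the fusion
    network, trained per fold with a fold-derived seed) or a baseline
    kind string (``"svm"``, ``"rf"``, ``"cnn"``, ``"lstm"``).  Every
    subject is tested exactly once; folds partition the subject set.
    """
    subjects, first_idx = np.unique(dataset.subject_ids, return_index=True)
    subject_labels = dataset.labels[first_idx]
    if k > subjects.size:
        raise ValueError(f"k={k} exceeds the {subjects.size} available subjects")

    # stratify by label where possible; with k above the smallest class
    # count (e.g. leave-one-subject-out) fall back to an unstratified split
    if k <= np.bincount(subject_labels).min():
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignments: dict[str, int] = {}
    per_fold_accuracy: list[float] = []
    cm = np.zeros((2, 2), dtype=int)
    subj_scores: dict[str, float] = {}
    subj_true: dict[str, int] = {}

    for fold, (train_subj_idx, test_subj_idx) in enumerate(
        skf.split(subjects, subject_labels)
    ):
        train_subjects = set(subjects[train_subj_idx])
        test_subjects = subjects[test_subj_idx]
        train_mask = np.isin(dataset.subject_ids, list(train_subjects))
        train_set = dataset.subset(np.flatnonzero(train_mask))
        test_set = dataset.subset(np.flatnonzero(~train_mask))

        if isinstance(model_spec, str):
            fitted = train_baseline(model_spec, train_set, seed=seed + fold)
            probs = fitted.predict_proba(test_set)
        else:
            fitted = train(model_spec, train_set, seed=model_spec.seed + fold)
            probs = predict_proba(fitted, test_set)

        correct = 0
        for s in test_subjects:
            fold_assignments[str(s)] = fold
            mask = test_set.subject_ids == s
            score = float(probs[mask, 1].mean())
            true = int(test_set.labels[mask][0])
            pred = int(score >= 0.5)
            subj_scores[str(s)] = score
            subj_true[str(s)] = true
            cm[true, pred] += 1
            correct += int(pred == true)
        per_fold_accuracy.append(correct / len(test_subjects))

    scores = np.array([subj_scores[str(s)] for s in subjects])
    truths = np.array([subj_true[str(s)] for s in subjects])
    roc_points, auc = roc_auc(scores, truths)
    mean_accuracy = float(np.trace(cm) / cm.sum())
    return CVReport(
        fold_assignments=fold_assignments,
        per_fold_accuracy=per_fold_accuracy,
        mean_accuracy=mean_accuracy,
        confusion_matrix=cm.tolist(),
        roc_points=roc_points,
        auc=auc,
        subject_scores=subj_scores,
        subject_labels=subj_true,
    )


def tsne_embed(
    feature_matrix: np.ndarray,
    perplexity: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE embedding of a feature matrix (deterministic per seed)."""
    from sklearn.manifold import TSNE

    x = np.asarray(feature_matrix, dtype=float)
    if x.shape[0] < 3 * perplexity:
        raise ValueError(
            f"t-SNE needs at least 3 x perplexity = {3 * perplexity:.0f} "
            f"samples, got {x.shape[0]}"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(x)
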
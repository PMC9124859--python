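"""Splits, classification metrics, and the regularisation ablation grid.

Two split schemes are used: a per-subject stratified 90/10 split of the 84
trials, and a group-level scheme that cuts each subject's trials into 10
near-equal parts, sends one part per subject to the pooled test set and the
other nine to the pooled training set.  Metrics are the five standard
multiclass scores (accuracy, Cohen's kappa, macro precision/recall/F1) plus
macro one-vs-rest ROC-AUC and the full confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (cohen_kappa_score, confusion_matrix,
                             precision_recall_fscore_support, roc_auc_score)

from .preprocess import MI_CLASSES

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "AblationSpec",
    "subject_split",
    "group_split",
    "compute_metrics",
    "run_ablation",
]


@dataclass
class SplitPlan:
    """Disjoint train/test assignment covering every trial."""

    scheme: str
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        overlap = np.intersect1d(self.train_indices, self.test_indices)
        if overlap.size:
            raise ValueError("train and test sets overlap")


@dataclass
class MetricsReport:
    """The five headline scores plus confusion matrix and macro AUC."""

    confusion: np.ndarray
    accuracy: float
    kappa: float
    precision: float
    recall: float
    f1: float
    auc: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    classes: tuple[str, ...] = MI_CLASSES

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "per_class": self.per_class,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.classes),
                            columns=list(self.classes))


@dataclass(frozen=True)
class AblationSpec:
    """The four-variant regularisation grid: dropout x batch norm."""

    variants: tuple[tuple[str, bool, bool], ...] = (
        ("full", True, True),
        ("no_dropout", False, True),
        ("no_batchnorm", True, False),
        ("neither", False, False),
    )


def subject_split(
    labels,
    fraction: float = 0.9,
    seed: int = 0,
) -> SplitPlan:
    """Stratified-by-class random train/test split of one subject's trials.

    Per class, ``round((1 - fraction) * n_class)`` trials (at least one) go
    to the test set; with 21 trials per class and fraction 0.9 this is the
    19/2 split.
    """
    labels = np.asarray(labels).astype(str)
    if len(labels) < 10:
        raise ValueError("need at least 10 trials for a 90/10 split")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1 "
                         "(an empty train or test set is useless)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 trials")
        n_test = max(1, int(round((1.0 - fraction) * len(idx))))
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    return SplitPlan(scheme="subject",
                     train_indices=np.sort(train_idx),
                     test_indices=np.sort(test_idx),
                     seed=seed,
                     detail={"fraction": fraction})


def group_split(
    subject_ids,
    folds: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Group-level split: per subject, 1 of ``folds`` near-equal parts to test.

    Each subject's trials are shuffled and cut into ``folds`` parts whose
    sizes differ by at most one; one randomly chosen part joins the pooled
    test set, the rest the pooled training set.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    subject_ids = np.asarray(subject_ids)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    part_sizes: dict[str, list[int]] = {}
    for subject in np.unique(subject_ids):
        idx = np.flatnonzero(subject_ids == subject)
        if len(idx) < folds:
            raise ValueError(
                f"subject {subject} has {len(idx)} trials, fewer than "
                f"{folds} folds")
        perm = rng.permutation(idx)
        parts = np.array_split(perm, folds)
        part_sizes[str(subject)] = [len(p) for p in parts]
        test_part = rng.integers(folds)
        for k, part in enumerate(parts):
            (test_idx if k == test_part else train_idx).extend(part)
    return SplitPlan(scheme="group",
                     train_indices=np.sort(train_idx),
                     test_indices=np.sort(test_idx),
                     seed=seed,
                     detail={"folds": folds, "part_sizes": part_sizes})


def compute_metrics(probabilities, true_labels,
                    classes: tuple[str, ...] = MI_CLASSES) -> MetricsReport:
    """Score argmax predictions and one-vs-rest ROC curves.

    Macro averaging throughout; a class never predicted contributes
    precision 0.  AUC for a class absent from the test labels is skipped in
    the macro average.
    """
    probs = np.asarray(probabilities, dtype=float)
    y_true = np.asarray(true_labels).astype(str)
    if probs.ndim != 2 or probs.shape[0] != len(y_true):
        raise ValueError("need one probability row per label")
    if probs.shape[1] != len(classes):
        raise ValueError(f"expected {len(classes)} class columns")
    unknown = set(y_true) - set(classes)
    if unknown:
        raise ValueError(f"labels outside {classes}: {sorted(unknown)}")
    if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probabilities must lie on the simplex")
    y_pred = np.asarray(classes)[probs.argmax(axis=1)]
    conf = confusion_matrix(y_true, y_pred, labels=list(classes))
    accuracy = float(np.trace(conf)) / max(conf.sum(), 1)
    kappa = (float(cohen_kappa_score(y_true, y_pred, labels=list(classes)))
             if len(set(y_true)) > 1 else 0.0)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(classes), average=None, zero_division=0)
    present = np.isin(classes, np.unique(y_true))
    macro_p = float(prec[present].mean())
    macro_r = float(rec[present].mean())
    macro_f = float(f1[present].mean())
    aucs = {}
    for k, cls in enumerate(classes):
        truth = (y_true == cls).astype(int)
        if truth.min() == truth.max():
            continue  # class absent (or alone): AUC undefined
        aucs[cls] = float(roc_auc_score(truth, probs[:, k]))
    macro_auc = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    per_class = {
        cls: {"precision": float(prec[k]), "recall": float(rec[k]),
              "f1": float(f1[k]), **({"auc": aucs[cls]} if cls in aucs else {})}
        for k, cls in enumerate(classes)
    }
    return MetricsReport(confusion=conf, accuracy=accuracy, kappa=kappa,
                         precision=macro_p, recall=macro_r, f1=macro_f,
                         auc=macro_auc, per_class=per_class, classes=classes)


def run_ablation(
    assembled: np.ndarray,
    labels,
    split: SplitPlan,
    base_params: dict | None = None,
    spec: AblationSpec | None = None,
) -> dict[str, MetricsReport]:
    """Train the four dropout/batch-norm variants on one identical split."""
    from .dualcnn import DualCNNClassifier

    if spec is None:
        spec = AblationSpec()
    labels = np.asarray(labels).astype(str)
    if len(np.unique(labels)) < len(MI_CLASSES):
        raise ValueError("ablation needs all four MI classes present")
    params = dict(base_params or {})
    reports: dict[str, MetricsReport] = {}
    Xtr, ytr = assembled[split.train_indices], labels[split.train_indices]
    Xte, yte = assembled[split.test_indices], labels[split.test_indices]
    for name, use_dropout, use_bn in spec.variants:
        clf = DualCNNClassifier(**params,
                                use_spatial_dropout=use_dropout,
                                use_batchnorm=use_bn)
        clf.fit(Xtr, ytr)
        probs = _full_probs(clf, Xte)
        reports[name] = compute_metrics(probs, yte)
    return reports


def _full_probs(clf, X) -> np.ndarray:
    """Probabilities expanded to all four class columns in MI order."""
    probs = clf.predict_proba(X)
    out = np.zeros((len(probs), len(MI_CLASSES)))
    for j, cls in enumerate(clf.classes_):
        out[:, MI_CLASSES.index(cls)] = probs[:, j]
    return out
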
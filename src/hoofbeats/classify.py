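"""Triplet embedding and supervised gait / individual classification.

Three adjacent raw interval durations (t_k, t_k+1, t_k+2) are embedded in
two dimensions with UMAP — durations are deliberately left unscaled, since
tempo differences are themselves diagnostic of gait — and the embedding
coordinates (V1, V2) feed a random-forest classifier (1000 trees, 70/30
stratified split). The report carries the out-of-bag error, the training
confusion matrix, one-vs-rest ROC/AUC per class from tree-vote fractions,
variable importances, an error-vs-trees trace, and two accuracies: the
pooled train+test figure and the test-only figure (the generalization
metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import train_test_split

from .errors import InvalidParameterError, StratificationError, ValidationError
from .rhythm import TripletTable

__all__ = ["EmbeddingResult", "ClassifierReport", "embed_triplets", "train_classifier", "roc_curves"]


@dataclass
class EmbeddingResult:
    """2-D UMAP coordinates aligned row-for-row with the input triplets."""

    coords: np.ndarray            # (n, 2): V1, V2
    individual_id: np.ndarray
    gait: np.ndarray
    n_neighbors: int
    min_dist: float
    metric: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "V1": self.coords[:, 0],
                "V2": self.coords[:, 1],
                "individual_id": self.individual_id,
                "gait": self.gait,
            }
        )


def embed_triplets(
    triplets: TripletTable,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
    metric: str = "euclidean",
) -> EmbeddingResult:
    """Embed interval triplets into (V1, V2) with seeded UMAP.

    The embedding is deterministic under a fixed seed and input order for
    ordinary (jittered) data. Inputs dominated by exactly duplicated rows
    (e.g. noise-free simulations) can defeat the spectral initialization,
    in which case the upstream library falls back to an initialization
    that is not reproducible; a warning from umap-learn marks that case.
    """
    if len(triplets) < n_neighbors + 1:
        raise InvalidParameterError(
            f"need at least n_neighbors+1={n_neighbors + 1} triplets, got {len(triplets)}"
        )
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(triplets.values), dtype=float)
    return EmbeddingResult(
        coords=coords,
        individual_id=triplets.individual_id,
        gait=triplets.gait,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        seed=seed,
    )


@dataclass
class ClassifierReport:
    label_kind: str               # "gait" | "individual"
    classes: list
    oob_error_pct: float
    confusion: pd.DataFrame       # training-set, true x predicted
    per_class_auc: dict
    overall_accuracy_pct: float   # pooled train+test predictions
    test_accuracy_pct: float      # held-out only
    importance: dict              # V1/V2 -> Gini importance
    error_trace: pd.DataFrame     # test error vs number of trees
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    # per-row scores for ROC reconstruction
    train_scores: np.ndarray = field(repr=False, default=None)
    test_scores: np.ndarray = field(repr=False, default=None)
    y_train: np.ndarray = field(repr=False, default=None)
    y_test: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "label_kind": self.label_kind,
            "classes": [str(c) for c in self.classes],
            "oob_error_pct": self.oob_error_pct,
            "confusion": self.confusion.to_dict(),
            "per_class_auc": {str(k): v for k, v in self.per_class_auc.items()},
            "overall_accuracy_pct": self.overall_accuracy_pct,
            "test_accuracy_pct": self.test_accuracy_pct,
            "importance": self.importance,
            "seed": self.seed,
        }


def train_classifier(
    embedding: EmbeddingResult,
    label: str = "gait",
    n_trees: int = 1000,
    train_fraction: float = 0.7,
    seed: int = 0,
    trace_points: int = 20,
) -> ClassifierReport:
    """Random-forest classification of (V1, V2) by gait or individual.

    The split is stratified by the supervising label and seeded. OOB error
    and the confusion matrix describe the training fit; AUCs are
    one-vs-rest on training vote fractions; the error trace tracks test
    error as trees accumulate (a check that 1000 trees are enough).
    """
    if label not in ("gait", "individual"):
        raise InvalidParameterError("label must be 'gait' or 'individual'")
    y = np.asarray(embedding.gait if label == "gait" else embedding.individual_id)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValidationError("need >=2 classes")
    if not 0 < train_fraction < 1:
        raise InvalidParameterError("train_fraction must be in (0, 1)")
    X = embedding.coords
    idx = np.arange(len(y))
    try:
        tr, te = train_test_split(
            idx, train_size=train_fraction, stratify=y, random_state=seed
        )
    except ValueError as exc:
        raise StratificationError(f"stratified split failed: {exc}") from exc
    if set(y[tr]) != set(classes) or set(y[te]) != set(classes):
        missing = sorted((set(classes) - set(y[tr])) | (set(classes) - set(y[te])))
        raise StratificationError(f"class(es) absent from a split: {missing}")

    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X[tr], y[tr])

    train_pred = rf.predict(X[tr])
    test_pred = rf.predict(X[te])
    confusion = pd.DataFrame(
        confusion_matrix(y[tr], train_pred, labels=classes),
        index=classes,
        columns=classes,
    )
    train_scores = rf.predict_proba(X[tr])
    test_scores = rf.predict_proba(X[te])
    per_class_auc = {}
    for k, cls in enumerate(rf.classes_):
        fpr, tpr, _ = roc_curve(y[tr] == cls, train_scores[:, k])
        per_class_auc[cls] = float(_auc(fpr, tpr))

    n_correct = int(np.sum(train_pred == y[tr])) + int(np.sum(test_pred == y[te]))
    overall = 100.0 * n_correct / len(y)
    test_acc = 100.0 * float(np.mean(test_pred == y[te]))

    trace = _error_trace(rf, X[te], y[te], trace_points)
    order = list(rf.classes_)
    return ClassifierReport(
        label_kind=label,
        classes=order,
        oob_error_pct=100.0 * (1.0 - float(rf.oob_score_)),
        confusion=confusion,
        per_class_auc=per_class_auc,
        overall_accuracy_pct=overall,
        test_accuracy_pct=test_acc,
        importance={
            "V1": float(rf.feature_importances_[0]),
            "V2": float(rf.feature_importances_[1]),
        },
        error_trace=trace,
        train_idx=tr,
        test_idx=te,
        seed=seed,
        train_scores=train_scores,
        test_scores=test_scores,
        y_train=y[tr],
        y_test=y[te],
    )


def _error_trace(rf, X_test, y_test, n_points: int) -> pd.DataFrame:
    """Cumulative-vote test error at ~n_points tree counts."""
    n_trees = len(rf.estimators_)
    checkpoints = np.unique(
        np.linspace(1, n_trees, min(n_points, n_trees)).astype(int)
    )
    class_index = {c: i for i, c in enumerate(rf.classes_)}
    votes = np.zeros((X_test.shape[0], len(rf.classes_)))
    errors, done = [], 0
    for cp in checkpoints:
        for tree in rf.estimators_[done:cp]:
            pred = tree.predict(X_test).astype(int)
            votes[np.arange(len(pred)), pred] += 1
        done = cp
        pred_cls = rf.classes_[votes.argmax(axis=1)]
        errors.append(1.0 - float(np.mean(pred_cls == y_test)))
    return pd.DataFrame({"n_trees": checkpoints, "test_error": errors})


def roc_curves(report: ClassifierReport, subset: str = "train") -> dict:
    """One-vs-rest (FPR, TPR, AUC) per class from stored vote fractions."""
    if subset == "train":
        scores, y = report.train_scores, report.y_train
    elif subset == "test":
        scores, y = report.test_scores, report.y_test
    else:
        raise InvalidParameterError("subset must be 'train' or 'test'")
    if len(set(y)) < 2:
        raise ValidationError("ROC undefined for a single class")
    out = {}
    for k, cls in enumerate(report.classes):
        fpr, tpr, _ = roc_curve(y == cls, scores[:, k])
        out[cls] = {"fpr": fpr, "tpr": tpr, "auc": float(_auc(fpr, tpr))}
    return out
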
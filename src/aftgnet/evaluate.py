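"""Stratified k-fold evaluation harness and the metric suite.

The protocol mirrors the classifier's intended use: features are extracted
per image (so no fold can leak into another through feature extraction), a
standardizer and the classifier are fit on each training split only, and the
reported fold metrics come from the checkpoint with the best validation
accuracy. Precision/recall/F1 are reported for the disease-positive class at
a 0.5 threshold on the softmax probability; AUC is the rank statistic.
Confusion matrices are row-normalized to percentages of the true-label count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .fusion import cross_weighted_fuse
from .hog import extract_hog
from .io import ImageRecord, to_working_size
from .model import AttnMLP, AttnMLPConfig, train
from .tda import extract_tda

DEFAULT_K = 20
DECISION_THRESHOLD = 0.5


@dataclass
class FoldReport:
    fold_index: int
    metrics: dict[str, Optional[float]]
    confusion: np.ndarray  # 2x2 row-normalized percentages
    n_train: int
    n_val: int
    val_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "metrics": self.metrics,
            "confusion_percent": np.asarray(self.confusion).tolist(),
            "n_train": self.n_train,
            "n_val": self.n_val,
            "val_ids": self.val_ids,
        }


@dataclass
class CVSummary:
    mean: dict[str, float]
    std: dict[str, float]
    pooled_confusion: np.ndarray
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "std": self.std,
            "pooled_confusion_percent": np.asarray(self.pooled_confusion).tolist(),
            "k": self.k,
            "seed": self.seed,
        }


def stratified_kfold(
    labels: Sequence[int], k: int = DEFAULT_K, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified folds; each class must have >= k members."""
    y = np.asarray(labels, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(f"class {cls} has only {cnt} samples, fewer than k={k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(y)), y)]


def compute_metrics(
    probs: np.ndarray, labels: Sequence[int], threshold: float = DECISION_THRESHOLD
) -> dict[str, Optional[float]]:
    """Positive-class precision/recall/F1, accuracy, and rank-based AUC.

    ``probs`` is (n, 2); the positive (disease) class is column 1. With a
    single-class batch the AUC is undefined and reported as None.
    """
    probs = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if len(y) == 0:
        raise ValueError("empty prediction batch")
    p1 = probs[:, 1]
    pred = (p1 >= threshold).astype(np.int64)
    out: dict[str, Optional[float]] = {
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
        "f1": float(f1_score(y, pred, zero_division=0)),
        "accuracy": float(accuracy_score(y, pred)),
    }
    if np.unique(y).size < 2:
        import warnings

        warnings.warn("single-class batch: AUC undefined, reported as None")
        out["auc"] = None
    else:
        out["auc"] = float(roc_auc_score(y, p1))
    return out


def confusion_percent(labels: Sequence[int], predictions: Sequence[int]) -> np.ndarray:
    """2x2 confusion matrix normalized per true class to percentages."""
    y = np.asarray(labels, dtype=np.int64)
    pred = np.asarray(predictions, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("confusion matrix needs both classes present")
    cm = confusion_matrix(y, pred, labels=[0, 1]).astype(np.float64)
    return 100.0 * cm / cm.sum(axis=1, keepdims=True)


def extract_fused_features(records: Sequence[ImageRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-image fused descriptors (n, 2560) and their alpha weights."""
    feats, alphas = [], []
    for rec in records:
        rec = to_working_size(rec)
        fused = cross_weighted_fuse(extract_hog(rec).values, extract_tda(rec).values)
        feats.append(fused.values)
        alphas.append(fused.alpha)
    return np.asarray(feats), np.asarray(alphas)


def run_cv(
    records: Sequence[ImageRecord],
    cfg: Optional[AttnMLPConfig] = None,
    k: int = DEFAULT_K,
    seed: int = 0,
    features: Optional[np.ndarray] = None,
) -> tuple[CVSummary, list[FoldReport]]:
    """Cross-validated evaluation of the full pipeline.

    Per fold: standardizer fit on the training split, classifier trained on
    the standardized training features with the validation split driving
    checkpoint selection, metrics computed on the validation split.
    Precomputed ``features`` may be passed to avoid re-extracting; they must
    be per-image quantities (leakage-free by construction).
    """
    labels = np.asarray([r.label for r in records], dtype=np.int64)
    ids = [r.id for r in records]
    cfg = cfg if cfg is not None else AttnMLPConfig()
    if features is None:
        features, _ = extract_fused_features(records)

    folds = stratified_kfold(labels, k=k, seed=seed)
    reports: list[FoldReport] = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for i, (tr, va) in enumerate(folds):
        scaler = StandardScaler().fit(features[tr])
        X_tr = scaler.transform(features[tr])
        X_va = scaler.transform(features[va])
        fold_cfg = AttnMLPConfig(
            **{**cfg.__dict__, "seed": (seed * 100003 + i) % (2**31)}
        )
        model, _ = train(X_tr, labels[tr], X_va, labels[va], fold_cfg)
        probs = model.predict_proba(X_va)
        metrics = compute_metrics(probs, labels[va])
        pred = (probs[:, 1] >= DECISION_THRESHOLD).astype(np.int64)
        conf = confusion_percent(labels[va], pred) if np.unique(labels[va]).size == 2 else np.full((2, 2), np.nan)
        reports.append(
            FoldReport(
                fold_index=i,
                metrics=metrics,
                confusion=conf,
                n_train=len(tr),
                n_val=len(va),
                val_ids=[ids[j] for j in va],
            )
        )
        pooled_true.append(labels[va])
        pooled_pred.append(pred)

    metric_names = ["precision", "recall", "f1", "accuracy", "auc"]
    mean, std = {}, {}
    for name in metric_names:
        vals = [r.metrics[name] for r in reports if r.metrics[name] is not None]
        mean[name] = float(np.mean(vals))
        std[name] = float(np.std(vals))
    pooled = confusion_percent(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return CVSummary(mean=mean, std=std, pooled_confusion=pooled, k=k, seed=seed), reports
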
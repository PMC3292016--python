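"""Classifier evaluation: Sn/Sp/Acc, ROC/AUC, and stratified k-fold CV.

Sensitivity, specificity, and accuracy are reported as percentages::

    Sn  = 100 * TP / (TP + FN)
    Sp  = 100 * TN / (TN + FP)
    Acc = 100 * (TP + TN) / (TP + TN + FP + FN)

Cross-validation metrics are exposed in both conventions — pooled over
all folds' confusion counts, and as the mean of per-fold accuracies (the
headline figure). ROC curves sweep all unique score thresholds; AUC is
the trapezoidal area, which equals the probability that a random positive
outscores a random negative (ties counted half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from afpkit.classifier import GridSpec, TrainedModel, fit_grid, predict
from afpkit.features import FeatureVector, stack_features


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )


def confusion(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    """Binary confusion counts (positive class = 1)."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    if len(t) == 0:
        raise ValueError("empty label vectors")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(Sn, Sp, Acc) as percentages.

    When a class is absent (TP+FN == 0 for Sn, TN+FP == 0 for Sp) the
    corresponding metric is undefined and returned as NaN, never as 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    sn = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    sp = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    acc = 100.0 * (c.tp + c.tn) / c.total
    return sn, sp, acc


@dataclass(frozen=True)
class ROCCurve:
    """A receiver operating characteristic curve.

    ``fpr``/``tpr`` run from (0, 0) to (1, 1), nondecreasing; ``auc`` is
    the trapezoidal area under the curve.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc(scores: Sequence[float], y_true: Sequence[int]) -> ROCCurve:
    """ROC curve over all unique score thresholds (ties grouped) with
    trapezoidal AUC.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y_true, dtype=int)
    if len(s) != len(t):
        raise ValueError("scores and labels differ in length")
    if len(np.unique(t)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresh = _sk_roc_curve(t, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresh, auc=auc)


@dataclass
class CVResult:
    """Stratified k-fold cross-validation outcome.

    ``fold_metrics`` has one row per fold (TP/TN/FP/FN, Sn, Sp, Acc).
    ``pooled`` aggregates confusion counts over folds; ``mean_acc`` is the
    mean of per-fold accuracies (the headline figure), ``pooled_acc`` the
    accuracy of the pooled counts. ``roc_curve`` is built from the pooled
    out-of-fold scores.
    """

    fold_counts: list[ConfusionCounts]
    fold_metrics: pd.DataFrame
    pooled: ConfusionCounts
    mean_acc: float
    pooled_acc: float
    sn: float
    sp: float
    roc_curve: ROCCurve
    seed: int
    fold_models: list[TrainedModel] = field(default_factory=list)
    oof_scores: Optional[np.ndarray] = None

    @property
    def auc(self) -> float:
        return self.roc_curve.auc


def kfold_cv(
    X: Union[Sequence[FeatureVector], np.ndarray],
    y: Sequence[int],
    k: int = 10,
    seed: int = 0,
    grid: Optional[GridSpec] = None,
    threshold: float = 0.5,
    keep_models: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation with the grid-searched RBF-SVM.

    Each fold's model is trained (with its own inner grid search, seeded
    from ``seed``) on the other k-1 folds and applied to the held-out
    fold. Fold assignment, grid search, and probability calibration are
    all deterministic given ``seed``.

    Raises
    ------
    ValueError
        If either class has fewer than k members.
    """
    if isinstance(X, np.ndarray):
        mat = np.asarray(X, dtype=float)
    else:
        mat = stack_features(list(X))
    y_arr = np.asarray(y, dtype=int)
    if mat.shape[0] != len(y_arr):
        raise ValueError("features and labels differ in length")
    for cls in (0, 1):
        n_cls = int(np.sum(y_arr == cls))
        if n_cls < k:
            raise ValueError(
                f"class {cls} has {n_cls} members, fewer than k={k} folds"
            )
    if grid is None:
        grid = GridSpec.default(seed=seed)

    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_counts: list[ConfusionCounts] = []
    fold_rows = []
    models: list[TrainedModel] = []
    oof_scores = np.full(len(y_arr), np.nan)
    for fold_i, (train_idx, test_idx) in enumerate(outer.split(mat, y_arr)):
        model, _ = fit_grid(mat[train_idx], y_arr[train_idx], grid=grid)
        probs, calls = predict(model, mat[test_idx], threshold=threshold)
        oof_scores[test_idx] = probs
        c = confusion(y_arr[test_idx], calls)
        sn, sp, acc = metrics(c)
        fold_counts.append(c)
        fold_rows.append(
            {
                "fold": fold_i,
                "n": len(test_idx),
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
                "sn": sn, "sp": sp, "acc": acc,
            }
        )
        if keep_models:
            models.append(model)

    pooled = fold_counts[0]
    for c in fold_counts[1:]:
        pooled = pooled + c
    sn, sp, pooled_acc = metrics(pooled)
    fold_metrics = pd.DataFrame(fold_rows)
    mean_acc = float(fold_metrics["acc"].mean())
    curve = roc(oof_scores, y_arr)
    return CVResult(
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        pooled=pooled,
        mean_acc=mean_acc,
        pooled_acc=pooled_acc,
        sn=sn,
        sp=sp,
        roc_curve=curve,
        seed=seed,
        fold_models=models,
        oof_scores=oof_scores,
    )


def compare_encoders(
    features_by_encoder: Mapping[str, Sequence[FeatureVector]],
    y: Sequence[int],
    k: int = 10,
    seed: int = 0,
    grid: Optional[GridSpec] = None,
) -> pd.DataFrame:
    """Run identical k-fold CV (same seed, hence same folds) for several
    encodings of the same sequences and tabulate accuracy and AUC.

    Returns one row per encoder: encoder, mean_acc, pooled_acc, sn, sp,
    auc.
    """
    rows = []
    for name, feats in features_by_encoder.items():
        result = kfold_cv(feats, y, k=k, seed=seed, grid=grid)
        rows.append(
            {
                "encoder": name,
                "mean_acc": result.mean_acc,
                "pooled_acc": result.pooled_acc,
                "sn": result.sn,
                "sp": result.sp,
                "auc": result.auc,
            }
        )
    return pd.DataFrame(rows)
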
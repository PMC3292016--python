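"""Grid-searched RBF-kernel SVM classification.

The classifier is a soft-margin support vector machine with a radial
basis function kernel, k(x, x') = exp(-gamma ||x - x'||^2). The penalty
parameter C trades margin width against training error; gamma sets the
kernel width. Both are chosen by exhaustive grid search maximizing
stratified 5-fold cross-validation accuracy, the standard protocol for
this family of sequence classifiers. The quadratic program itself is
delegated to scikit-learn's libsvm binding; this module owns the
surrounding contract: min-max feature scaling to [0, 1] (statistics
persisted with the model), deterministic seeding, tie-breaking toward
smaller C then smaller gamma (smoother models), and Platt-calibrated
probability outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from afpkit.features import FeatureVector, stack_features
from afpkit.sequences import CANONICAL_ALPHABET

_MODEL_FORMAT_VERSION = 1


def _pow2(start: int, stop: int, step: int = 2) -> tuple[float, ...]:
    return tuple(2.0**e for e in range(start, stop + 1, step))


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter lattice for the (C, gamma) grid search."""

    c_values: tuple[float, ...] = _pow2(-5, 15)
    gamma_values: tuple[float, ...] = _pow2(-15, 3)
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_values or not self.gamma_values:
            raise ValueError("both hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.c_values) or any(
            g <= 0 for g in self.gamma_values
        ):
            raise ValueError("C and gamma values must be positive")
        if self.folds < 2:
            raise ValueError("grid-search folds must be >= 2")

    @classmethod
    def default(cls, seed: int = 0) -> "GridSpec":
        """The standard libsvm-guide lattice: C in 2^-5..2^15, gamma in
        2^-15..2^3, both stepping by 2^2."""
        return cls(seed=seed)

    @classmethod
    def coarse(cls, seed: int = 0) -> "GridSpec":
        """A reduced 5 x 4 lattice for quick runs and tests."""
        return cls(
            c_values=_pow2(-3, 9, 3),
            gamma_values=_pow2(-9, 0, 3),
            seed=seed,
        )


@dataclass
class TrainedModel:
    """A fitted RBF-SVM with its scaling statistics and metadata.

    Feature scaling maps each dimension to [0, 1] via the training-set
    min/max; at prediction time out-of-range values are clipped.
    Metadata records the feature scheme, alphabet ordering, PSSM
    squashing choice, and seed so a persisted model is unambiguous.
    """

    scheme: str
    c: float
    gamma: float
    estimator: CalibratedClassifierCV
    feature_min: np.ndarray
    feature_max: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return len(self.feature_min)

    def scale(self, X: np.ndarray) -> np.ndarray:
        span = self.feature_max - self.feature_min
        span = np.where(span == 0, 1.0, span)
        return np.clip((X - self.feature_min) / span, 0.0, 1.0)


def _as_matrix(
    X: Union[Sequence[FeatureVector], np.ndarray],
) -> tuple[np.ndarray, Optional[str]]:
    if isinstance(X, np.ndarray):
        return np.asarray(X, dtype=float), None
    feats = list(X)
    if feats and isinstance(feats[0], FeatureVector):
        return stack_features(feats), feats[0].scheme
    return np.asarray(feats, dtype=float), None


def fit_grid(
    X: Union[Sequence[FeatureVector], np.ndarray],
    y: Sequence[int],
    grid: Optional[GridSpec] = None,
    scheme: Optional[str] = None,
    metadata: Optional[dict] = None,
    class_weight: Optional[Union[str, dict]] = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Grid-search (C, gamma) by stratified k-fold CV accuracy and refit
    on all data with probability calibration.

    Ties are broken toward the smallest C, then the smallest gamma. The
    returned report has one row per (C, gamma) pair with its mean CV
    accuracy, in grid order. ``class_weight`` (e.g. ``"balanced"``) is
    passed through to the SVM for imbalanced designs; the default is no
    weighting, matching balanced training sets.

    Raises
    ------
    ValueError
        If only one class is present or feature dimensions disagree.
    """
    if grid is None:
        grid = GridSpec.default()
    mat, inferred_scheme = _as_matrix(X)
    scheme = scheme or inferred_scheme or "unknown"
    y_arr = np.asarray(y, dtype=int)
    if mat.shape[0] != len(y_arr):
        raise ValueError(
            f"{mat.shape[0]} feature rows but {len(y_arr)} labels"
        )
    classes = np.unique(y_arr)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    fmin = mat.min(axis=0)
    fmax = mat.max(axis=0)
    span = np.where(fmax - fmin == 0, 1.0, fmax - fmin)
    scaled = (mat - fmin) / span

    cv = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=grid.seed)
    splits = list(cv.split(scaled, y_arr))

    best: Optional[tuple[float, float, float]] = None  # (acc, C, gamma)
    rows = []
    for c in grid.c_values:
        for g in grid.gamma_values:
            accs = []
            for train_idx, test_idx in splits:
                clf = SVC(C=c, gamma=g, kernel="rbf", class_weight=class_weight)
                clf.fit(scaled[train_idx], y_arr[train_idx])
                accs.append(
                    float(
                        np.mean(clf.predict(scaled[test_idx]) == y_arr[test_idx])
                    )
                )
            mean_acc = float(np.mean(accs))
            rows.append({"C": c, "gamma": g, "cv_accuracy": mean_acc})
            # strict > keeps the first (smallest C, then gamma) on ties
            if best is None or mean_acc > best[0]:
                best = (mean_acc, c, g)

    assert best is not None
    _, c_best, g_best = best
    # Platt-style sigmoid calibration over cross-validated decision values;
    # the final SVC is refit on all data (ensemble=False).
    min_class = int(np.bincount(y_arr).min())
    calib_folds = max(2, min(grid.folds, min_class))
    final = CalibratedClassifierCV(
        estimator=SVC(
            C=c_best, gamma=g_best, kernel="rbf", class_weight=class_weight
        ),
        method="sigmoid",
        cv=StratifiedKFold(
            n_splits=calib_folds, shuffle=True, random_state=grid.seed
        ),
        ensemble=False,
    )
    final.fit(scaled, y_arr)
    meta = {
        "alphabet": CANONICAL_ALPHABET,
        "seed": grid.seed,
        "grid_folds": grid.folds,
        "pssm400_squash": "sigmoid",
        "class_weight": class_weight,
    }
    if metadata:
        meta.update(metadata)
    model = TrainedModel(
        scheme=scheme,
        c=c_best,
        gamma=g_best,
        estimator=final,
        feature_min=fmin,
        feature_max=fmax,
        metadata=meta,
    )
    return model, pd.DataFrame(rows)


def predict(
    model: TrainedModel,
    X: Union[Sequence[FeatureVector], np.ndarray],
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class probabilities and binary calls at ``threshold``.

    A call is positive iff probability >= threshold, so threshold 0 calls
    everything positive and raising the threshold can only turn positive
    calls negative.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    mat, scheme = _as_matrix(X)
    if scheme is not None and scheme != model.scheme:
        raise ValueError(
            f"feature scheme {scheme!r} does not match model scheme "
            f"{model.scheme!r}"
        )
    if mat.shape[1] != model.dim:
        raise ValueError(
            f"feature dimension {mat.shape[1]} does not match model "
            f"dimension {model.dim}"
        )
    scaled = model.scale(mat)
    pos_col = int(np.where(model.estimator.classes_ == 1)[0][0])
    probs = model.estimator.predict_proba(scaled)[:, pos_col]
    calls = (probs >= threshold).astype(int)
    return probs, calls


class ModelFileError(ValueError):
    """Corrupted or incompatible persisted model."""


def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Persist a trained model as a single versioned archive."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "scheme": model.scheme,
        "c": model.c,
        "gamma": model.gamma,
        "estimator": model.estimator,
        "feature_min": model.feature_min,
        "feature_max": model.feature_max,
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path: Union[str, Path]) -> TrainedModel:
    """Load a model saved by :func:`save_model`.

    Raises
    ------
    ModelFileError
        On a truncated/corrupt file, a format-version mismatch, a missing
        field, or an alphabet ordering different from this package's.
    """
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFileError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ModelFileError(f"{path}: not a model archive")
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ModelFileError(
            f"{path}: format_version {version!r} unsupported "
            f"(expected {_MODEL_FORMAT_VERSION})"
        )
    required = ("scheme", "c", "gamma", "estimator", "feature_min", "feature_max")
    for key in required:
        if key not in payload:
            raise ModelFileError(f"{path}: missing field {key!r}")
    meta = payload.get("metadata", {})
    alphabet = meta.get("alphabet")
    if alphabet is not None and alphabet != CANONICAL_ALPHABET:
        raise ModelFileError(
            f"{path}: model was trained with alphabet ordering "
            f"{alphabet!r}, incompatible with {CANONICAL_ALPHABET!r}"
        )
    return TrainedModel(
        scheme=payload["scheme"],
        c=payload["c"],
        gamma=payload["gamma"],
        estimator=payload["estimator"],
        feature_min=np.asarray(payload["feature_min"], dtype=float),
        feature_max=np.asarray(payload["feature_max"], dtype=float),
        metadata=meta,
    )
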
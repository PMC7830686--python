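"""Gradient-boosted staging under cross-validation.

The classifier itself is an off-the-shelf gradient-boosting implementation
(LightGBM when available, scikit-learn's histogram gradient boosting
otherwise); this module owns the evaluation protocol around it:
per-fold z-score standardization fitted on the training fold only (no
leakage), stratified k-fold or leave-one-subject-out splitting, and a
pooled confusion matrix in which every epoch is predicted exactly once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold

from ppgsleep.features import FEATURE_NAMES
from ppgsleep.metrics import ConfusionMatrix

logger = logging.getLogger(__name__)

try:
    from lightgbm import LGBMClassifier

    _HAVE_LIGHTGBM = True
except ImportError:  # pragma: no cover - exercised only without lightgbm
    _HAVE_LIGHTGBM = False

DEFAULT_MODEL_PARAMS = {"max_depth": 8, "n_estimators": 200, "learning_rate": 0.1}


@dataclass
class CvPlan:
    """Cross-validation protocol: stratified k-fold over epochs (default
    k = 10) or leave-one-subject-out, with optional per-fold z-scoring."""

    strategy: str = "kfold"
    k: int = 10
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in ("kfold", "leave_one_subject_out"):
            raise ValueError("strategy must be 'kfold' or 'leave_one_subject_out'")
        if self.strategy == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")


@dataclass
class Scaler:
    """Per-feature z-score parameters fitted on a training fold.  Features
    with zero spread are passed through unscaled (flagged)."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


@dataclass
class CvResult:
    predictions: np.ndarray
    true: np.ndarray
    fold_assignment: np.ndarray
    confusion: ConfusionMatrix
    classes: tuple[str, ...] = field(default_factory=tuple)


def standardize(train: np.ndarray, apply_to: np.ndarray | None = None):
    """Z-score ``apply_to`` (default: the training set itself) using the
    training set's statistics only.

    Returns ``(standardized, scaler)``.
    """
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    degenerate = sd == 0
    if np.any(degenerate):
        logger.debug("%d feature(s) with zero SD passed through unscaled", int(degenerate.sum()))
        sd = np.where(degenerate, 1.0, sd)
        mean = np.where(degenerate, 0.0, mean)
    scaler = Scaler(mean=mean, sd=sd)
    target = train if apply_to is None else np.asarray(apply_to, dtype=float)
    return scaler.transform(target), scaler


def make_classifier(params: dict | None = None, seed: int = 0):
    """The gradient-boosting model: LightGBM when installed, otherwise
    scikit-learn's HistGradientBoostingClassifier with matched settings."""
    p = dict(DEFAULT_MODEL_PARAMS)
    if params:
        p.update(params)
    if _HAVE_LIGHTGBM:
        return LGBMClassifier(
            max_depth=p["max_depth"],
            n_estimators=p["n_estimators"],
            learning_rate=p["learning_rate"],
            random_state=seed,
            n_jobs=1,
            verbose=-1,
        )
    from sklearn.ensemble import HistGradientBoostingClassifier

    return HistGradientBoostingClassifier(
        max_depth=p["max_depth"],
        max_iter=p["n_estimators"],
        learning_rate=p["learning_rate"],
        random_state=seed,
    )


def _canonical_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Reorder feature columns canonically so predictions are invariant to
    the column order of the input table."""
    if set(FEATURE_NAMES) <= set(X.columns):
        extra = [c for c in X.columns if c not in FEATURE_NAMES]
        return X.loc[:, list(FEATURE_NAMES) + sorted(extra)]
    return X.loc[:, sorted(X.columns)]


def cross_validate(
    X: pd.DataFrame | np.ndarray,
    y,
    plan: CvPlan | None = None,
    model_params: dict | None = None,
    groups=None,
) -> CvResult:
    """Run the full cross-validation protocol and pool the predictions.

    Every epoch is held out exactly once; each fold trains a fresh model on
    fold-standardized features.  A fold whose training split misses a class
    is retained with a warning.
    """
    if plan is None:
        plan = CvPlan()
    if isinstance(X, pd.DataFrame):
        X = _canonical_columns(X)
        columns = list(X.columns)
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        columns = [f"f{i}" for i in range(values.shape[1])]
    y = np.asarray([str(v) for v in y])
    if len(values) != len(y):
        raise ValueError("features and labels must have equal length")
    classes = tuple(sorted(set(y)))

    if plan.strategy == "kfold":
        splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        splits = splitter.split(values, y)
    else:
        if groups is None:
            raise ValueError("leave_one_subject_out requires groups (subject ids)")
        splits = LeaveOneGroupOut().split(values, y, groups=np.asarray(groups))

    predictions = np.empty(len(y), dtype=object)
    fold_assignment = np.full(len(y), -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(splits):
        y_train = y[train_idx]
        if len(set(y_train)) < len(classes):
            warnings.warn(f"fold {fold}: training split is missing a class", stacklevel=2)
        X_train, X_test = values[train_idx], values[test_idx]
        if plan.standardize:
            X_train, scaler = standardize(X_train)
            X_test = scaler.transform(values[test_idx])
        model = make_classifier(model_params, seed=plan.seed)
        model.fit(pd.DataFrame(X_train, columns=columns), y_train)
        predictions[test_idx] = model.predict(pd.DataFrame(X_test, columns=columns))
        fold_assignment[test_idx] = fold

    if np.any(fold_assignment < 0):
        raise RuntimeError("some epochs were never assigned to a test fold")
    predictions = predictions.astype(str)
    cm = ConfusionMatrix.from_labels(y, predictions, classes=classes)
    return CvResult(
        predictions=predictions,
        true=y,
        fold_assignment=fold_assignment,
        confusion=cm,
        classes=classes,
    )
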
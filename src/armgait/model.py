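"""Ordinal score prediction: random forest with nested cross-validation.

The classifier treats the 0-4 impairment scale as a 5-class problem (the
ordinal structure is honoured downstream by quadratic kappa weighting).
Features are standardised to zero mean and unit variance with statistics
fitted on training rows only; hyperparameters are selected by an inner
cross-validation loop run inside each outer training set, so the outer test
fold never influences scaling or model selection.

Fold assignment defaults to grouping by participant — all trials of one
person share a fold — which prevents identity leakage when participants
contribute multiple trials.  ``grouping="by_trial"`` splits trials
independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, GroupKFold, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import ModelConfig
from .features import FEATURE_COLUMNS, ID_COLUMNS, LABEL_COLUMN

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    pass


@dataclass
class FoldRecord:
    """Bookkeeping for one outer fold (used for reporting and leakage audits)."""

    fold: int
    train_index: np.ndarray
    test_index: np.ndarray
    best_params: dict
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    accuracy: float


@dataclass
class NestedCVResult:
    predictions: pd.DataFrame       # trial_id, participant_id, predicted, median_score
    fold_accuracies: List[float]
    folds: List[FoldRecord]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class TrainedModel:
    """A fitted standardiser + forest with its training schema."""

    pipeline: Pipeline
    feature_columns: Tuple[str, ...]
    best_params: dict
    classes: np.ndarray
    format_version: int = MODEL_FORMAT_VERSION

    @property
    def importances(self) -> pd.Series:
        """Per-feature importance weights (they sum to 1)."""
        forest = self.pipeline.named_steps["forest"]
        return pd.Series(forest.feature_importances_, index=list(self.feature_columns))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump({"format_version": self.format_version,
                     "feature_columns": self.feature_columns,
                     "best_params": self.best_params,
                     "classes": self.classes,
                     "pipeline": self.pipeline}, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(Path(path))
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ModelError(f"unsupported model file version {blob.get('format_version')}")
        return cls(pipeline=blob["pipeline"], feature_columns=tuple(blob["feature_columns"]),
                   best_params=blob["best_params"], classes=blob["classes"])


def _matrix(table: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ModelError(f"feature table missing column(s): {missing}")
    X = table.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy(dtype=int)
    groups = table["participant_id"].to_numpy()
    return X, y, groups


def _pipeline(seed: int, config: ModelConfig) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("forest", RandomForestClassifier(random_state=seed,
                                          class_weight=config.class_weight)),
    ])


def _outer_splits(X, y, groups, config: ModelConfig):
    if config.grouping == "by_participant":
        n_groups = len(np.unique(groups))
        k = min(config.outer_folds, n_groups)
        if k < config.outer_folds:
            logger.warning("only %d participant groups; reducing outer folds to %d",
                           n_groups, k)
        return list(GroupKFold(n_splits=k).split(X, y, groups))
    cv = KFold(n_splits=config.outer_folds, shuffle=True,
               random_state=config.random_seed)
    return list(cv.split(X, y))


def _inner_cv(train_groups, config: ModelConfig, fold_seed: int):
    if config.grouping == "by_participant":
        k = min(config.inner_folds, len(np.unique(train_groups)))
        return GroupKFold(n_splits=k)
    return KFold(n_splits=config.inner_folds, shuffle=True, random_state=fold_seed)


def _grid_search(X_tr, y_tr, groups_tr, config: ModelConfig, seed: int) -> GridSearchCV:
    if len(np.unique(y_tr)) < 2:
        logger.warning("training portion contains a single class; fitting anyway")
    gs = GridSearchCV(
        _pipeline(seed, config), config.param_grid,
        scoring="accuracy",
        cv=_inner_cv(groups_tr, config, seed),
        n_jobs=1, refit=True,
    )
    gs.fit(X_tr, y_tr, groups=groups_tr if config.grouping == "by_participant" else None)
    return gs


def nested_cv_evaluate(table: pd.DataFrame, config: ModelConfig) -> NestedCVResult:
    """Out-of-fold predictions and per-fold accuracies from nested CV.

    For each of ``outer_folds`` outer folds, an inner grid search over the
    hyperparameter grid selects the forest settings by inner-CV accuracy on
    the training portion; the winning pipeline (standardiser refitted on the
    full training portion) then predicts the held-out fold.  Every row
    receives exactly one held-out prediction.  Fixed seed => identical fold
    assignments, chosen hyperparameters and predictions.
    """
    X, y, groups = _matrix(table)
    if len(y) < config.outer_folds * 2:
        raise ModelError(f"need at least {config.outer_folds * 2} rows for "
                         f"{config.outer_folds}-fold nested CV")
    if len(np.unique(y)) < 2:
        raise ModelError("need at least 2 distinct labels")

    predicted = np.full(len(y), -1, dtype=int)
    fold_accuracies: List[float] = []
    folds: List[FoldRecord] = []
    for f, (tr, te) in enumerate(_outer_splits(X, y, groups, config)):
        seed = config.random_seed + f
        gs = _grid_search(X[tr], y[tr], groups[tr], config, seed)
        yhat = gs.best_estimator_.predict(X[te])
        predicted[te] = yhat
        acc = float(np.mean(yhat == y[te]))
        fold_accuracies.append(acc)
        scaler = gs.best_estimator_.named_steps["scale"]
        folds.append(FoldRecord(
            fold=f, train_index=tr, test_index=te, best_params=dict(gs.best_params_),
            scaler_mean=scaler.mean_.copy(), scaler_scale=scaler.scale_.copy(),
            accuracy=acc))
        logger.info("outer fold %d: accuracy %.3f, params %s", f, acc, gs.best_params_)

    assert np.all(predicted >= 0), "every row must receive one held-out prediction"
    preds = table.loc[:, list(ID_COLUMNS)].copy()
    preds["predicted"] = predicted
    preds[LABEL_COLUMN] = y
    return NestedCVResult(predictions=preds, fold_accuracies=fold_accuracies, folds=folds)


def fit_final(table: pd.DataFrame, config: ModelConfig) -> TrainedModel:
    """Standardiser + forest fitted on all rows, hyperparameters chosen by
    a full-data inner CV grid search."""
    X, y, groups = _matrix(table)
    if len(np.unique(y)) < 2:
        raise ModelError("need at least 2 distinct labels")
    gs = _grid_search(X, y, groups, config, config.random_seed)
    return TrainedModel(pipeline=gs.best_estimator_,
                        feature_columns=tuple(FEATURE_COLUMNS),
                        best_params=dict(gs.best_params_),
                        classes=gs.best_estimator_.named_steps["forest"].classes_)


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Apply a trained model to a feature table; integer 0-4 scores per row."""
    missing = [c for c in model.feature_columns if c not in features.columns]
    if missing:
        raise ModelError(f"feature table missing column(s): {missing}")
    X = features.loc[:, list(model.feature_columns)].to_numpy(dtype=float)
    out = features.loc[:, [c for c in ID_COLUMNS if c in features.columns]].copy()
    out["predicted"] = model.pipeline.predict(X).astype(int)
    return out


def permutation_null(
    pred: Sequence[int], ref: Sequence[int], n_reps: int = 1000,
    seed: int = 0,
) -> Tuple[float, float, np.ndarray]:
    """Null distribution of accuracy under label permutation.

    Shuffles the reference labels relative to the predictions ``n_reps``
    times and records the agreement rate; returns (mean, sd, samples).
    Used to check that a fitted model's accuracy reflects signal rather
    than class imbalance.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref).copy()
    rng = np.random.default_rng(seed)
    samples = np.empty(n_reps)
    for i in range(n_reps):
        rng.shuffle(ref)
        samples[i] = np.mean(pred == ref)
    return float(samples.mean()), float(samples.std(ddof=1)), samples
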
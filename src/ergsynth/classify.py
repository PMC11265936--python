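"""Sex classification of ERG feature vectors under class imbalance.

Implements the evaluation protocol around the augmentation study: the
confusion-matrix metric set (precision, recall/sensitivity, specificity,
balanced accuracy, F1), a random-oversampling-with-replacement baseline, a
random-forest classifier tuned by stratified 3-fold grid search, and the
three-condition comparison (original / oversampled / synthesized) in which
every condition is evaluated on the same untouched, unbalanced real test
split.  The minority class (male) is the positive class throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .features import feature_columns, feature_table
from .gan import AugmentationPolicy, CGANResults, balance_with_synthetic
from .postprocess import LowpassSpec, fourier_lowpass
from .simulate import ErgWaveform

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "CvSpec",
    "UndefinedMetricError",
    "confusion_counts",
    "compute_metrics",
    "f1_score",
    "balanced_accuracy",
    "random_oversample",
    "fit_and_evaluate",
    "run_conditions",
    "ConditionReport",
    "CONDITIONS",
]

CONDITIONS = ("original", "oversampled", "synthesized")


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for the given confusion counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Precision, recall (= sensitivity), specificity, balanced accuracy, F1."""

    precision: float
    recall: float
    specificity: float
    balanced_accuracy: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ba": self.balanced_accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity, "f1": self.f1,
        }


@dataclass(frozen=True)
class CvSpec:
    """Model-selection protocol: stratified k-fold grid search.

    The hyperparameter grid covers tree count, depth and features per split.
    ``inner_split`` echoes the nominal train:validation ratio of the
    protocol; the stratified folds implement the actual splitting.
    """

    n_folds: int = 3
    stratified: bool = True
    inner_split: tuple[int, int] = (80, 20)
    n_estimators: tuple[int, ...] = (100, 300)
    max_depth: tuple[int | None, ...] = (None, 5, 10)
    max_features: tuple[str | None, ...] = (None, "sqrt")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if min(self.inner_split) <= 0:
            raise ValueError("split ratio parts must be positive")
        if not (self.n_estimators and self.max_depth and self.max_features):
            raise ValueError("hyperparameter grid must be non-empty")

    def grid(self) -> dict[str, list]:
        return {
            "n_estimators": list(self.n_estimators),
            "max_depth": list(self.max_depth),
            "max_features": list(self.max_features),
        }


def confusion_counts(y_true: Sequence, y_pred: Sequence, positive) -> ConfusionCounts:
    """2×2 tally with the designated positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels) > 2:
        raise ValueError(f"binary labels required, got {sorted(map(str, labels))}")
    if len(labels) == 2 and positive not in labels:
        raise ValueError(f"positive label {positive!r} not among observed labels {labels}")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall: 2PR/(P+R)."""
    if precision + recall == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall = 0")
    return 2.0 * precision * recall / (precision + recall)


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """(sensitivity + specificity) / 2."""
    return (sensitivity + specificity) / 2.0


def compute_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Metric set from confusion counts; zero denominators raise, never return 0."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no actual positives")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no actual negatives")
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predicted positives")
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    specificity = c.tn / (c.tn + c.fp)
    return ClassificationMetrics(
        precision=precision,
        recall=recall,
        specificity=specificity,
        balanced_accuracy=balanced_accuracy(recall, specificity),
        f1=f1_score(precision, recall),
    )


def random_oversample(
    feature_rows: pd.DataFrame, minority_label: str = "male",
    seed: int = 0, label_col: str = "sex",
) -> pd.DataFrame:
    """Upsample the minority class with replacement until class counts equal.

    All original rows are retained; an already balanced input is returned
    unchanged.
    """
    counts = feature_rows[label_col].value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present for oversampling")
    n_minority = int(counts.get(minority_label, 0))
    if n_minority == 0:
        raise ValueError(f"minority label {minority_label!r} absent")
    n_majority = int(counts.drop(minority_label).max())
    deficit = n_majority - n_minority
    if deficit <= 0:
        return feature_rows.copy()
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero((feature_rows[label_col] == minority_label).to_numpy())
    extra = rng.choice(pool, size=deficit, replace=True)
    return pd.concat(
        [feature_rows, feature_rows.iloc[extra]], ignore_index=True
    )


def _rows_to_xy(rows: pd.DataFrame, cols: list[str], positive: str, label_col: str):
    X = rows[cols].to_numpy(dtype=float)
    y = (rows[label_col] == positive).astype(int).to_numpy()
    return X, y


def fit_and_evaluate(
    train_rows: pd.DataFrame,
    test_rows: pd.DataFrame,
    cv: CvSpec | None = None,
    positive: str = "male",
    label_col: str = "sex",
):
    """Grid-searched random forest; metrics on the held-out test rows.

    The feature set follows the stimulus of the rows (four LA3 parameters,
    two flicker parameters).  Model selection maximizes balanced accuracy
    over stratified folds; the best model is refit on all training rows and
    scored on the test rows with the minority class positive.
    """
    cv = cv or CvSpec()
    stimuli = set(train_rows["stimulus"].unique()) | set(test_rows["stimulus"].unique())
    if len(stimuli) != 1:
        raise ValueError(f"train/test rows must share one stimulus, got {sorted(stimuli)}")
    cols = feature_columns(stimuli.pop())
    if test_rows[label_col].nunique() < 2:
        raise UndefinedMetricError("balanced accuracy undefined on a single-class test set")
    X_train, y_train = _rows_to_xy(train_rows, cols, positive, label_col)
    X_test, y_test = _rows_to_xy(test_rows, cols, positive, label_col)
    folds = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    search = GridSearchCV(
        RandomForestClassifier(random_state=cv.seed, n_jobs=1),
        param_grid=cv.grid(),
        scoring="balanced_accuracy",
        cv=folds,
        n_jobs=1,
        refit=True,
    )
    search.fit(X_train, y_train)
    y_pred = search.predict(X_test)
    counts = confusion_counts(y_test, y_pred, positive=1)
    return search, compute_metrics(counts)


def _hash_rows(rows: pd.DataFrame) -> str:
    payload = rows.sort_values(list(rows.columns)).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class ConditionReport:
    """Three-condition evaluation for one stimulus, tied to one test split."""

    stimulus: str
    metrics: dict[str, ClassificationMetrics]
    train_counts: dict[str, dict[str, int]]
    test_hash: str
    n_test: int
    exclusions: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond in CONDITIONS:
            m = self.metrics[cond]
            rows.append({"dataset_analysis": cond, "ba": m.balanced_accuracy,
                         "precision": m.precision, "recall": m.recall, "f1": m.f1})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({
            "stimulus": self.stimulus,
            "metrics": {c: self.metrics[c].as_dict() for c in CONDITIONS},
            "train_counts": self.train_counts,
            "test_hash": self.test_hash,
            "n_test": self.n_test,
            "exclusions": self.exclusions,
        }, indent=2)


def run_conditions(
    real_train: Sequence[ErgWaveform],
    test: Sequence[ErgWaveform],
    generator: CGANResults,
    policy: AugmentationPolicy | None = None,
    cv: CvSpec | None = None,
    lowpass: LowpassSpec | None = None,
    seed: int = 0,
    initial_size: int | None = None,
    positive: str = "male",
) -> ConditionReport:
    """Evaluate original / oversampled / synthesized training sets.

    All three conditions share the identical real test feature rows (their
    hash is recorded in the report).  The synthesized condition appends
    GAN-generated minority waveforms, low-pass smooths them, and extracts
    their features the same way as for real records.
    """
    policy = policy or AugmentationPolicy()
    cv = cv or CvSpec()
    lowpass = lowpass or LowpassSpec()
    stimulus = generator.stimulus

    train_ft = feature_table(real_train)
    test_ft = feature_table(test)
    if test_ft.table.empty:
        raise ValueError("no test rows survived feature extraction")
    test_rows = test_ft.table
    test_hash = _hash_rows(test_rows)

    def smooth(w: ErgWaveform) -> ErgWaveform:
        return fourier_lowpass(w, lowpass)

    augmented = balance_with_synthetic(
        list(real_train), generator, policy, seed=seed,
        initial_size=initial_size, postprocess=smooth,
    )
    synth_ft = feature_table(augmented)

    exclusions = {
        "original": train_ft.n_excluded,
        "test": test_ft.n_excluded,
        "synthesized": synth_ft.n_excluded,
    }
    train_sets = {
        "original": train_ft.table,
        "oversampled": random_oversample(train_ft.table, minority_label=positive, seed=seed),
        "synthesized": synth_ft.table,
    }
    metrics: dict[str, ClassificationMetrics] = {}
    counts: dict[str, dict[str, int]] = {}
    for cond in CONDITIONS:
        rows = train_sets[cond]
        _, metrics[cond] = fit_and_evaluate(rows, test_rows, cv=cv, positive=positive)
        counts[cond] = rows["sex"].value_counts().to_dict()
    return ConditionReport(
        stimulus=stimulus, metrics=metrics, train_counts=counts,
        test_hash=test_hash, n_test=len(test_rows), exclusions=exclusions,
    )
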
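"""Per-recording supervised evaluation: can a classifier told the true
track labels separate the spikes of one recording?

The protocol is 5-fold stratified cross-validation of an RBF-kernel SVM
(library defaults: C = 1, gamma = 1 / (d * Var(X)), one-vs-one multiclass)
on each feature set, scored with accuracy (correct predictions / total
predictions) and macro-averaged precision, recall and F1. The fold
assignment is computed after sorting the rows into a canonical order, so
the report is invariant to the row order of the feature matrix given a
fixed seed. A random-forest alternative classifier is available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix


class EvaluationError(ValueError):
    """The labeled data cannot support the requested cross-validation."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to evaluate and with what parameters.

    ``svm_rbf`` uses the scikit-learn defaults (C=1.0, gamma="scale",
    one-vs-one); ``random_forest`` uses the library default forest. Extra
    entries in ``params`` are passed through to the estimator.
    """

    kind: str = "svm_rbf"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm_rbf", "random_forest"):
            raise EvaluationError(f"unknown classifier kind {self.kind!r}")

    def build(self):
        if self.kind == "svm_rbf":
            return SVC(kernel="rbf", C=1.0, gamma="scale", **self.params)
        return RandomForestClassifier(random_state=self.seed, **self.params)


@dataclass(frozen=True)
class EvalReport:
    """Cross-validated metrics for one recording and one feature set."""

    dataset: str
    feature_set: str
    fold_accuracy: tuple
    fold_precision: tuple
    fold_recall: tuple
    fold_macro_f1: tuple
    n_classes: int
    chance: float

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def precision(self) -> float:
        return float(np.mean(self.fold_precision))

    @property
    def recall(self) -> float:
        return float(np.mean(self.fold_recall))

    @property
    def macro_f1(self) -> float:
        return float(np.mean(self.fold_macro_f1))

    def to_row(self) -> dict:
        return {
            "dataset": self.dataset,
            "feature_set": self.feature_set,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "macro_f1": self.macro_f1,
            "n_classes": self.n_classes,
            "chance": self.chance,
        }


def chance_level(labels, *, majority: bool = False) -> float:
    """Random-chance accuracy baseline.

    Defaults to ``1 / k`` for ``k`` distinct labels (the convention for the
    near-balanced designs these recordings have); ``majority=True`` returns
    the majority-class frequency instead.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise EvaluationError("chance level needs at least one label")
    _, counts = np.unique(labels, return_counts=True)
    if majority:
        return float(counts.max() / counts.sum())
    return 1.0 / len(counts)


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sort rows by (label, feature values) so fold assignment does not
    depend on the incoming row order."""
    keys = tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)) + (y,)
    return np.lexsort(keys)


def run_cv(
    F: FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec(),
    folds: int = 5,
    dataset: str = "",
) -> EvalReport:
    """Stratified k-fold cross-validation of one feature matrix.

    Every class must have at least ``folds`` members (otherwise some test
    folds would miss the class entirely); the offending class is named in
    the error. Deterministic given ``spec.seed``.
    """
    X = np.asarray(F.X, dtype=np.float64)
    y = np.asarray(F.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise EvaluationError("cross-validation needs at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt < folds:
            raise EvaluationError(
                f"class {cls!r} has only {cnt} spikes (< {folds} folds)"
            )
    order = _canonical_order(X, y)
    X, y = X[order], y[order]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    acc, prec, rec, f1 = [], [], [], []
    for train, test in skf.split(X, y):
        clf = spec.build()
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        acc.append(accuracy_score(y[test], pred))
        prec.append(precision_score(y[test], pred, average="macro", zero_division=0))
        rec.append(recall_score(y[test], pred, average="macro", zero_division=0))
        f1.append(f1_score(y[test], pred, average="macro", zero_division=0))
    return EvalReport(
        dataset=dataset,
        feature_set=F.feature_set,
        fold_accuracy=tuple(acc),
        fold_precision=tuple(prec),
        fold_recall=tuple(rec),
        fold_macro_f1=tuple(f1),
        n_classes=len(classes),
        chance=chance_level(y),
    )


def rank_feature_sets(reports) -> pd.DataFrame:
    """Aggregate EvalReports across recordings into a feature-set ranking.

    Returns one row per feature set with the mean/median/quartiles of the
    per-recording mean accuracies, ordered by descending mean accuracy
    (ties broken by feature-set name). The attached ``best_per_dataset``
    attribute maps each dataset to its best-scoring feature set.
    """
    rows = pd.DataFrame([r.to_row() for r in reports])
    if rows.empty:
        raise EvaluationError("no reports to rank")
    g = rows.groupby("feature_set")["accuracy"]
    table = pd.DataFrame(
        {
            "mean": g.mean(),
            "median": g.median(),
            "q1": g.quantile(0.25),
            "q3": g.quantile(0.75),
            "n_datasets": g.size(),
        }
    )
    # stable sort: descending mean accuracy, ties broken by feature-set name
    table = table.sort_index().sort_values("mean", ascending=False, kind="mergesort")
    best = (
        rows.sort_values(["accuracy", "feature_set"], ascending=[False, True],
                         kind="mergesort")
        .groupby("dataset")
        .first()["feature_set"]
        .to_dict()
    )
    table.attrs["best_per_dataset"] = best
    return table
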
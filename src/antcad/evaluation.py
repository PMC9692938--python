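"""Pluggable classifiers and confusion-matrix metrics.

Classification itself is deliberately delegated: :class:`ClassifierSpec`
wraps the standard scikit-learn estimators (decision tree, SVM, KNN,
ensemble, naive Bayes, discriminant analysis) behind a uniform
fit/predict contract.  The metric algebra, by contrast, is authored here:
per-class one-vs-rest reductions of a multiclass confusion matrix into
TP/TN/FP/FN counts, the standard rate metrics (ACC, TPR, TNR, PPV, NPV, F1,
misclassification rate, Matthews correlation coefficient), and their
macro-averaged aggregation.

Zero-denominator rates (e.g. precision when nothing was predicted positive)
are defined as 0 and flagged on the report rather than propagating NaN.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .table import FeatureTable

__all__ = [
    "ClassifierSpec",
    "ConfusionMatrix",
    "BinaryCounts",
    "MetricReport",
    "confusion",
    "binary_counts",
    "metrics_from_counts",
    "macro_metrics",
    "evaluate",
    "cross_val_error",
]

logger = logging.getLogger(__name__)

CLASSIFIER_FAMILIES = (
    "decision_tree",
    "svm",
    "knn",
    "ensemble",
    "naive_bayes",
    "discriminant",
)

METRIC_NAMES = ("acc", "tpr", "tnr", "ppv", "npv", "f1", "mr", "mcc")


@dataclass
class ClassifierSpec:
    """A classifier family plus hyperparameters, built on demand.

    ``family`` picks one of the roster families; ``hyperparameters`` are
    passed to the underlying scikit-learn constructor, and ``seed`` fixes any
    internal randomness so repeated builds behave identically.
    """

    family: str = "knn"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; choose from {CLASSIFIER_FAMILIES}"
            )

    def build(self):
        hp = dict(self.hyperparameters)
        if self.family == "decision_tree":
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        if self.family == "svm":
            return SVC(random_state=self.seed, **hp)
        if self.family == "knn":
            hp.setdefault("n_neighbors", 1)
            return KNeighborsClassifier(**hp)
        if self.family == "ensemble":
            hp.setdefault("n_estimators", 100)
            return RandomForestClassifier(random_state=self.seed, **hp)
        if self.family == "naive_bayes":
            return GaussianNB(**hp)
        return LinearDiscriminantAnalysis(**hp)

    def describe(self) -> dict:
        est = self.build()
        return {
            "family": self.family,
            "seed": self.seed,
            "hyperparameters": {k: repr(v) for k, v in est.get_params().items()},
        }


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C integer grid; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.min() < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest reduction of a confusion matrix for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """Macro-averaged metric bundle plus per-class detail.

    ``acc`` is the overall accuracy from the confusion-matrix trace and
    ``mr = 1 - acc``; the remaining fields are macro averages of the
    per-class one-vs-rest values stored in ``per_class``.
    """

    acc: float
    tpr: float
    tnr: float
    ppv: float
    npv: float
    f1: float
    mr: float
    mcc: float
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    confusion: ConfusionMatrix | None = None
    zero_division_flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {
            "ACC": self.acc,
            "TPR": self.tpr,
            "TNR": self.tnr,
            "PPV": self.ppv,
            "NPV": self.npv,
            "F1": self.f1,
            "MR": self.mr,
            "MCC": self.mcc,
            "per_class": {
                str(c): {k.upper(): v for k, v in m.items()} for c, m in self.per_class.items()
            },
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.counts.tolist()
        if self.zero_division_flags:
            out["zero_division_flags"] = list(self.zero_division_flags)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def confusion(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int) -> ConfusionMatrix:
    """Tally the C x C confusion matrix from parallel label vectors."""
    yt = np.asarray(y_true, dtype=np.int64)
    yp = np.asarray(y_pred, dtype=np.int64)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D sequences")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (yt, yp), 1)
    return ConfusionMatrix(counts)


def binary_counts(matrix: ConfusionMatrix, c: int) -> BinaryCounts:
    """Reduce a multiclass confusion matrix to TP/TN/FP/FN for class ``c``."""
    if not 0 <= c < matrix.n_classes:
        raise ValueError(f"class index {c} outside [0, {matrix.n_classes})")
    m = matrix.counts
    tp = int(m[c, c])
    fn = int(m[c].sum()) - tp
    fp = int(m[:, c].sum()) - tp
    tn = matrix.total - tp - fn - fp
    return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_rate(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        logger.warning("metric %s has zero denominator; defined as 0", name)
        return 0.0
    return num / den


def metrics_from_counts(b: BinaryCounts, flags: list[str] | None = None) -> dict[str, float]:
    """Binary metric bundle from TP/TN/FP/FN counts.

    ACC = (TP+TN)/total, TPR = TP/(TP+FN), TNR = TN/(TN+FP),
    PPV = TP/(TP+FP), NPV = TN/(TN+FN), F1 = 2TP/(2TP+FP+FN),
    MR = (FP+FN)/total, and MCC = (TP*TN - FP*FN) /
    sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Any 0/0 is defined as 0 and noted
    in ``flags``.
    """
    if b.total == 0:
        raise ValueError("cannot compute metrics from zero samples")
    if flags is None:
        flags = []
    tp, tn, fp, fn = float(b.tp), float(b.tn), float(b.fp), float(b.fn)
    total = float(b.total)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "acc": (tp + tn) / total,
        "tpr": _safe_rate(tp, tp + fn, "TPR", flags),
        "tnr": _safe_rate(tn, tn + fp, "TNR", flags),
        "ppv": _safe_rate(tp, tp + fp, "PPV", flags),
        "npv": _safe_rate(tn, tn + fn, "NPV", flags),
        "f1": _safe_rate(2 * tp, 2 * tp + fp + fn, "F1", flags),
        "mr": (fp + fn) / total,
        "mcc": _safe_rate(tp * tn - fp * fn, mcc_den, "MCC", flags),
    }


def macro_metrics(matrix: ConfusionMatrix) -> MetricReport:
    """Macro-average the per-class one-vs-rest metrics of a confusion matrix.

    Overall accuracy comes from the matrix trace (fraction of correctly
    classified samples) and MR = 1 - ACC, so the pair always sums to one.
    The macro TPR/TNR/PPV/NPV/F1/MCC are unweighted means over classes.
    """
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    per_class = {}
    for c in range(matrix.n_classes):
        per_class[c] = metrics_from_counts(binary_counts(matrix, c), flags)
    acc = float(np.trace(matrix.counts)) / matrix.total
    macro = {
        name: float(np.mean([per_class[c][name] for c in per_class]))
        for name in ("tpr", "tnr", "ppv", "npv", "f1", "mcc")
    }
    return MetricReport(
        acc=acc,
        mr=1.0 - acc,
        per_class=per_class,
        confusion=matrix,
        zero_division_flags=flags,
        **macro,
    )


def evaluate(spec: ClassifierSpec, train: FeatureTable, test: FeatureTable) -> MetricReport:
    """Fit the specified classifier on ``train`` and report on ``test``."""
    y_train = train.require_labels()
    y_test = test.require_labels()
    if train.n_features != test.n_features:
        raise ValueError("train and test tables have different feature counts")
    n_classes = max(y_train.n_categories, y_test.n_categories)
    est = spec.build()
    est.fit(train.X, y_train.codes)
    y_pred = np.asarray(est.predict(test.X), dtype=np.int64)
    return macro_metrics(confusion(y_test.codes, y_pred, n_classes))


def cross_val_error(
    table: FeatureTable,
    subset: Sequence[int],
    spec: ClassifierSpec | None = None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold mean misclassification rate on a feature subset.

    This is the wrapper objective for the selector: lower error means a
    better subset.  Every class must have at least ``folds`` members.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = table.require_labels()
    counts = np.bincount(y.codes, minlength=y.n_categories)
    present = counts[counts > 0]
    if present.min() < folds:
        raise ValueError(
            f"smallest class has {int(present.min())} samples; needs >= {folds} for {folds}-fold CV"
        )
    sub = table.select_features(subset)
    spec = spec or ClassifierSpec(family="knn", hyperparameters={"n_neighbors": 1})
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = []
    for tr_idx, te_idx in skf.split(sub.X, y.codes):
        est = spec.build()
        est.fit(sub.X[tr_idx], y.codes[tr_idx])
        pred = est.predict(sub.X[te_idx])
        errors.append(float(np.mean(pred != y.codes[te_idx])))
    return float(np.mean(errors))
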
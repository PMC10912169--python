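"""Classifier training and evaluation: metrics, splits, k-fold, LOSO.

Confusion-count metrics are implemented directly from their defining ratios
so they can be cross-checked against independent arithmetic; AUC uses the
rank (Mann-Whitney) formulation with ties counted one half.  Undefined
metrics (zero denominators, single-class folds) are reported as ``None``,
never silently as zero.  The positive class is "dysarthric" throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "CLASSIFIER_NAMES",
    "UndefinedMetricError",
    "ConfusionCounts",
    "EvalReport",
    "LabeledFeatureTable",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "f1_from_precision_recall",
    "auc",
    "make_classifier",
    "split_evaluate",
    "kfold_evaluate",
    "loso_evaluate",
]

POSITIVE_LABEL = "dysarthric"
NEGATIVE_LABEL = "healthy"
CLASSIFIER_NAMES = ("LDA", "NB", "KNN", "SVM", "BoostedTree")


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (or a class is absent for AUC)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    pos = np.asarray(y_true) == POSITIVE_LABEL
    pred_pos = np.asarray(y_pred) == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined for zero evaluated rows")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predicted positives")
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no actual positives")
    return c.tp / (c.tp + c.fn)


def f1_from_precision_recall(pre: float, rec: float) -> float:
    if pre + rec == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall = 0")
    return 2.0 * pre * rec / (pre + rec)


def f1(c: ConfusionCounts) -> float:
    return f1_from_precision_recall(precision(c), recall(c))


def auc(scores: Sequence[float], labels: Sequence[Any]) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(labels) == POSITIVE_LABEL
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def make_classifier(name: str, seed: int = 0, **config: Any) -> Pipeline:
    """Build one of the five supported models behind a z-score scaler.

    Hyperparameters are plain defaults: LDA without shrinkage, Gaussian NB,
    KNN with k=5 Euclidean, RBF-kernel SVM with C=1 and gamma='scale', and
    gradient-boosted trees (100 stumps of depth 3, learning rate 0.1).
    """
    if name == "LDA":
        clf = LinearDiscriminantAnalysis(**config)
    elif name == "NB":
        clf = GaussianNB(**config)
    elif name == "KNN":
        clf = KNeighborsClassifier(n_neighbors=config.pop("n_neighbors", 5), **config)
    elif name == "SVM":
        clf = SVC(C=config.pop("C", 1.0), kernel="rbf", gamma="scale", **config)
    elif name == "BoostedTree":
        clf = GradientBoostingClassifier(
            n_estimators=config.pop("n_estimators", 100),
            max_depth=config.pop("max_depth", 3),
            learning_rate=config.pop("learning_rate", 0.1),
            random_state=seed,
            **config,
        )
    else:
        raise ValueError(
            f"unknown classifier {name!r}; valid options: {', '.join(CLASSIFIER_NAMES)}"
        )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _positive_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous score for the positive class, preferring decision_function."""
    clf = model.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        scores = model.decision_function(X)
        if np.asarray(model.classes_)[-1] != POSITIVE_LABEL:
            scores = -scores
        return scores
    proba = model.predict_proba(X)
    pos_col = int(np.flatnonzero(np.asarray(model.classes_) == POSITIVE_LABEL)[0])
    return proba[:, pos_col]


@dataclass(frozen=True)
class LabeledFeatureTable:
    """Feature rows with class labels and subject identifiers."""

    features: pd.DataFrame
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        subjects = np.asarray(self.subject_ids, dtype=object)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subject_ids", subjects)
        n = len(self.features)
        if labels.size != n or subjects.size != n:
            raise ValueError("features, labels and subject_ids must have equal length")
        if any(not isinstance(s, str) for s in subjects):
            raise ValueError("subject_ids must be strings")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=np.float64)

    def subset(self, idx: np.ndarray) -> "LabeledFeatureTable":
        return LabeledFeatureTable(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
        )

    @classmethod
    def from_csv(cls, path: str) -> "LabeledFeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path} has no 'label' column")
        if "subject_id" in df.columns:
            subjects = df["subject_id"].fillna("").astype(str)
        else:
            subjects = pd.Series([""] * len(df))
        meta = {"label", "subject_id", "source_file"}
        feats = df[[c for c in df.columns if c not in meta]]
        return cls(
            features=feats,
            labels=df["label"].to_numpy(),
            subject_ids=subjects.to_numpy(),
        )

    def to_csv(self, path: str, source_files: Sequence[str] | None = None) -> None:
        out = self.features.copy()
        out["label"] = self.labels
        out["subject_id"] = self.subject_ids
        out["source_file"] = source_files if source_files is not None else ""
        out.to_csv(path, index=False)


@dataclass
class FoldResult:
    """Metrics for one evaluation fold; None marks an undefined metric."""

    fold: str
    counts: ConfusionCounts
    train_accuracy: float
    test_accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


@dataclass
class EvalReport:
    """Pooled (micro) metrics with per-fold breakdown and macro averages."""

    classifier_name: str
    protocol: str
    counts: ConfusionCounts
    train_accuracy: float
    test_accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def macro(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for key in ("test_accuracy", "precision", "recall", "f1", "auc"):
            vals = [getattr(f, key) for f in self.folds if getattr(f, key) is not None]
            out[key] = float(np.mean(vals)) if vals else None
        return out

    def to_dict(self) -> dict[str, Any]:
        return {
            "classifier": self.classifier_name,
            "protocol": self.protocol,
            "train_pct": 100.0 * self.train_accuracy,
            "test_pct": None if self.test_accuracy is None else 100.0 * self.test_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "counts": asdict(self.counts),
            "macro": self.macro,
            "folds": [f.to_dict() for f in self.folds],
        }


def _metric_or_none(fn, *args) -> float | None:
    try:
        return float(fn(*args))
    except UndefinedMetricError:
        return None


def _evaluate_fold(
    name: str,
    seed: int,
    train: LabeledFeatureTable,
    test: LabeledFeatureTable,
    fold_label: str,
    **config: Any,
) -> FoldResult:
    if len(set(train.labels)) < 2:
        raise ValueError(f"training split for {fold_label} has a single class")
    model = make_classifier(name, seed=seed, **config)
    model.fit(train.X, train.labels)
    train_acc = accuracy(confusion_from_predictions(train.labels, model.predict(train.X)))
    counts = confusion_from_predictions(test.labels, model.predict(test.X))
    scores = _positive_scores(model, test.X)
    return FoldResult(
        fold=fold_label,
        counts=counts,
        train_accuracy=train_acc,
        test_accuracy=_metric_or_none(accuracy, counts),
        precision=_metric_or_none(precision, counts),
        recall=_metric_or_none(recall, counts),
        f1=_metric_or_none(f1, counts),
        auc=_metric_or_none(auc, scores, test.labels),
    )


def _pool(name: str, protocol: str, folds: list[FoldResult]) -> EvalReport:
    total = folds[0].counts
    for f in folds[1:]:
        total = total + f.counts
    train_acc = float(np.mean([f.train_accuracy for f in folds]))
    return EvalReport(
        classifier_name=name,
        protocol=protocol,
        counts=total,
        train_accuracy=train_acc,
        test_accuracy=_metric_or_none(accuracy, total),
        precision=_metric_or_none(precision, total),
        recall=_metric_or_none(recall, total),
        f1=_metric_or_none(f1, total),
        auc=_macro_auc(folds),
        folds=folds,
    )


def _macro_auc(folds: list[FoldResult]) -> float | None:
    vals = [f.auc for f in folds if f.auc is not None]
    return float(np.mean(vals)) if vals else None


def split_evaluate(
    table: LabeledFeatureTable,
    classifier_name: str,
    train_fraction: float = 0.8,
    seed: int = 0,
    **config: Any,
) -> EvalReport:
    """Stratified train/test split evaluation (80:20 or 70:30 style)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        stratify=table.labels,
        shuffle=True,
    )
    fold = _evaluate_fold(
        classifier_name, seed,
        table.subset(train_idx), table.subset(test_idx),
        fold_label=f"split-{train_fraction:g}",
        **config,
    )
    return _pool(classifier_name, f"split:{train_fraction:g}", [fold])


def kfold_evaluate(
    table: LabeledFeatureTable,
    classifier_name: str,
    k: int = 5,
    seed: int = 0,
    **config: Any,
) -> EvalReport:
    """Stratified k-fold cross-validation with pooled confusion counts."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        _evaluate_fold(
            classifier_name, seed,
            table.subset(tr), table.subset(te),
            fold_label=f"fold-{i + 1}",
            **config,
        )
        for i, (tr, te) in enumerate(skf.split(table.X, table.labels))
    ]
    return _pool(classifier_name, f"kfold:{k}", folds)


def loso_evaluate(
    table: LabeledFeatureTable,
    classifier_name: str,
    seed: int = 0,
    **config: Any,
) -> EvalReport:
    """Leave-one-subject-out: one fold per distinct subject identifier."""
    if any(s == "" for s in table.subject_ids):
        raise ValueError("LOSO requires a non-empty subject_id for every row")
    subjects = sorted(set(table.subject_ids))
    if len(subjects) < 2:
        raise ValueError(f"LOSO requires >= 2 distinct subjects, got {len(subjects)}")
    folds = []
    for subject in subjects:
        test_mask = table.subject_ids == subject
        folds.append(
            _evaluate_fold(
                classifier_name, seed,
                table.subset(np.flatnonzero(~test_mask)),
                table.subset(np.flatnonzero(test_mask)),
                fold_label=f"subject-{subject}",
                **config,
            )
        )
    return _pool(classifier_name, "loso", folds)
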
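"""One-vs-one RBF SVM evaluation with k-fold cross-validation.

Three labelings of the five performance conditions are supported:

* ``arousal`` — excited/distressed -> high, relaxed/depressed -> low,
  neutral -> neutral (3 classes);
* ``valence`` — excited/relaxed -> positive, distressed/depressed ->
  negative, neutral -> neutral (3 classes);
* ``emotion`` — the five conditions themselves.

Evaluation mirrors the shuffle-then-split protocol: a seeded global
shuffle, contiguous partition into k equal folds, per-fold column
standardization fit on the training rows, one binary RBF SVM per class
pair (C(5,2) = 10 for five classes) and majority voting with ties broken
toward the lowest class index in scheme order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LabelScheme",
    "SCHEMES",
    "CVReport",
    "make_labels",
    "crossvalidate",
    "confusion",
]


@dataclass(frozen=True)
class LabelScheme:
    """Mapping from performance condition to classification class."""

    name: str
    mapping: dict
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = set(self.mapping.values()) - set(self.class_order)
        if missing:
            raise ValueError(f"classes {missing} absent from class_order")


SCHEMES: dict[str, LabelScheme] = {
    "arousal": LabelScheme(
        "arousal",
        {
            "excited": "high",
            "distressed": "high",
            "relaxed": "low",
            "depressed": "low",
            "neutral": "neutral",
        },
        ("high", "low", "neutral"),
    ),
    "valence": LabelScheme(
        "valence",
        {
            "excited": "positive",
            "relaxed": "positive",
            "distressed": "negative",
            "depressed": "negative",
            "neutral": "neutral",
        },
        ("positive", "negative", "neutral"),
    ),
    "emotion": LabelScheme(
        "emotion",
        {c: c for c in ("distressed", "excited", "depressed", "relaxed", "neutral")},
        ("distressed", "excited", "depressed", "relaxed", "neutral"),
    ),
}


def make_labels(conditions, scheme: LabelScheme | str) -> np.ndarray:
    """Map per-row condition labels to the scheme's classes."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    conditions = np.asarray(conditions)
    unknown = set(conditions) - set(scheme.mapping)
    if unknown:
        raise ValueError(f"conditions {sorted(unknown)} unknown to scheme {scheme.name!r}")
    return np.array([scheme.mapping[c] for c in conditions])


@dataclass
class CVReport:
    """Per-fold accuracies and the pooled row-normalized confusion matrix."""

    scheme: str
    class_order: tuple[str, ...]
    train_accuracy: np.ndarray  # percent, per fold
    test_accuracy: np.ndarray
    confusion_counts: np.ndarray  # (n_classes, n_classes), rows = actual
    seed: int
    hyperparameters: dict = field(default_factory=dict)
    empty_classes: list[str] = field(default_factory=list)

    @property
    def train_mean(self) -> float:
        return float(self.train_accuracy.mean())

    @property
    def train_sd(self) -> float:
        return float(self.train_accuracy.std(ddof=1))

    @property
    def test_mean(self) -> float:
        return float(self.test_accuracy.mean())

    @property
    def test_sd(self) -> float:
        return float(self.test_accuracy.std(ddof=1))

    def summary(self) -> str:
        return (
            f"{self.scheme}: train {self.train_mean:.2f} ± {self.train_sd:.2f}, "
            f"test {self.test_mean:.2f} ± {self.test_sd:.2f}"
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "class_order": list(self.class_order),
                "train_accuracy": self.train_accuracy.tolist(),
                "test_accuracy": self.test_accuracy.tolist(),
                "train_mean": self.train_mean,
                "train_sd": self.train_sd,
                "test_mean": self.test_mean,
                "test_sd": self.test_sd,
                "confusion_counts": self.confusion_counts.tolist(),
                "confusion_percent": confusion(self).tolist(),
                "seed": self.seed,
                "hyperparameters": self.hyperparameters,
                "empty_classes": self.empty_classes,
            },
            indent=2,
        )


class _OneVsOneSVM:
    """C(k,2) binary RBF SVMs with majority voting.

    Ties are broken deterministically toward the lowest class index in
    scheme order (``np.argmax`` keeps the first maximum).
    """

    def __init__(self, class_order, C=1.0, gamma="scale"):
        self.class_order = list(class_order)
        self.C = C
        self.gamma = gamma
        self.classifiers: list[tuple[int, int, SVC]] = []

    def fit(self, X, y):
        idx = {c: i for i, c in enumerate(self.class_order)}
        yi = np.array([idx[c] for c in y])
        present = sorted(set(yi))
        self.classifiers = []
        for a, b in combinations(present, 2):
            rows = (yi == a) | (yi == b)
            clf = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
            clf.fit(X[rows], (yi[rows] == b).astype(int))
            self.classifiers.append((a, b, clf))
        return self

    def predict(self, X):
        votes = np.zeros((len(X), len(self.class_order)), dtype=int)
        for a, b, clf in self.classifiers:
            pred = clf.predict(X)
            votes[pred == 0, a] += 1
            votes[pred == 1, b] += 1
        winners = np.argmax(votes, axis=1)  # first max -> lowest class index
        return np.array([self.class_order[w] for w in winners])

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)


def _fold_indices(n: int, k: int, rng: np.random.Generator, stratify_on=None):
    """Seeded shuffle, then contiguous partition into k folds."""
    if stratify_on is None:
        order = rng.permutation(n)
        return np.array_split(order, k)
    # stratified: shuffle within class, deal rows round-robin across folds
    folds = [[] for _ in range(k)]
    labels = np.asarray(stratify_on)
    offset = 0
    for c in pd.unique(labels):
        rows = rng.permutation(np.nonzero(labels == c)[0])
        for i, r in enumerate(rows):
            folds[(i + offset) % k].append(r)
        offset += len(rows)
    return [np.array(f) for f in folds]


def crossvalidate(
    features,
    labels,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    gamma="scale",
    scheme_name: str | None = None,
    class_order: tuple[str, ...] | None = None,
    stratified: bool = False,
    standardize: bool = True,
) -> CVReport:
    """k-fold one-vs-one SVM evaluation of a (reduced) feature matrix.

    ``features`` is an (n, d) array or DataFrame; ``labels`` the per-row
    class labels.  Columns are standardized using the training rows of
    each fold.  Raises if a class is missing from any training fold
    (pass ``stratified=True`` for class-balanced folds).
    """
    X = np.asarray(features.data if hasattr(features, "data") else features, dtype=float)
    y = np.asarray(labels)
    n = len(X)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k rows")
    if len(y) != n:
        raise ValueError("labels must match feature rows")
    classes = tuple(class_order) if class_order else tuple(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, k, rng, stratify_on=y if stratified else None)

    n_cls = len(classes)
    cidx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((n_cls, n_cls), dtype=int)
    train_acc, test_acc = [], []
    for f in range(k):
        test_rows = folds[f]
        train_rows = np.concatenate([folds[g] for g in range(k) if g != f])
        missing = set(classes) - set(y[train_rows])
        if missing:
            raise ValueError(
                f"class(es) {sorted(missing)} absent from training fold {f}; "
                "use stratified=True for class-balanced folds"
            )
        if standardize:
            scaler = StandardScaler().fit(X[train_rows])
            Xtr, Xte = scaler.transform(X[train_rows]), scaler.transform(X[test_rows])
        else:
            Xtr, Xte = X[train_rows], X[test_rows]
        model = _OneVsOneSVM(classes, C=C, gamma=gamma).fit(Xtr, y[train_rows])
        train_pred = model.predict(Xtr)
        test_pred = model.predict(Xte)
        train_acc.append(100.0 * np.mean(train_pred == y[train_rows]))
        test_acc.append(100.0 * np.mean(test_pred == y[test_rows]))
        for actual, pred in zip(y[test_rows], test_pred):
            conf[cidx[actual], cidx[pred]] += 1

    empty = [c for i, c in enumerate(classes) if conf[i].sum() == 0]
    return CVReport(
        scheme=scheme_name or "custom",
        class_order=classes,
        train_accuracy=np.array(train_acc),
        test_accuracy=np.array(test_acc),
        confusion_counts=conf,
        seed=seed,
        hyperparameters={"C": C, "gamma": str(gamma), "k": k, "standardize": standardize},
        empty_classes=empty,
    )


def confusion(report: CVReport) -> np.ndarray:
    """Row-normalized confusion matrix in percent (rows = actual class).

    Rows with no observations are all-zero and listed in
    ``report.empty_classes``.
    """
    counts = report.confusion_counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * counts / np.where(totals > 0, totals, 1.0), 0.0)
    return pct
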
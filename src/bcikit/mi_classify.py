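"""Training and evaluation of the six-classifier menu on feature vectors.

The menu covers random forest (100 trees), k-nearest neighbors (k=5),
linear-kernel SVM in a one-versus-rest arrangement, Gaussian naive Bayes,
L2-regularized logistic regression and a depth-10 decision tree — all via
scikit-learn, with hyperparameters pinned by :class:`ModelSpec`.

Evaluation reports accuracy, macro precision/recall/F1 and the full
confusion matrix; macro averaging matches a class-balanced four-class
design where the three averages coincide with their micro counterparts
only by accident.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ModelSpec", "EvalReport", "split_dataset", "train_model", "evaluate_model"]

ALGORITHMS = ("RF", "KNN", "SVM", "NB", "LR", "DT")


@dataclass
class ModelSpec:
    """A classifier choice with its pinned hyperparameters.

    Defaults: RF 100 trees, KNN k=5, SVM linear kernel one-versus-rest,
    Gaussian NB, LR with L2 penalty, DT max depth 10.
    """

    algorithm: str = "LR"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; pick from {ALGORITHMS}")

    def build(self):
        p = self.params
        if self.algorithm == "RF":
            return RandomForestClassifier(
                n_estimators=p.get("n_estimators", 100), random_state=self.seed
            )
        if self.algorithm == "KNN":
            return KNeighborsClassifier(n_neighbors=p.get("k", 5))
        if self.algorithm == "SVM":
            return OneVsRestClassifier(
                SVC(kernel=p.get("kernel", "linear"), random_state=self.seed)
            )
        if self.algorithm == "NB":
            return GaussianNB()
        if self.algorithm == "LR":
            # L2 penalty is the estimator default
            return LogisticRegression(
                max_iter=p.get("max_iter", 2000), random_state=self.seed
            )
        if self.algorithm == "DT":
            return DecisionTreeClassifier(
                max_depth=p.get("max_depth", 10), random_state=self.seed
            )
        raise AssertionError("unreachable")


def split_dataset(
    vectors: np.ndarray,
    labels,
    train_fraction: float = 0.8,
    seed: int = 0,
):
    """Stratified train/test split, reproducible for a fixed seed.

    Returns ``(X_train, X_test, y_train, y_test)``.  Classes with a single
    sample cannot be stratified and raise, naming the class.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    X = np.asarray(vectors, dtype=float)
    y = np.asarray(labels)
    counts = Counter(y.tolist())
    singletons = [c for c, n in counts.items() if n < 2]
    if singletons:
        raise ValueError(f"classes with a single sample cannot be split: {singletons}")
    return train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed, shuffle=True
    )


def train_model(X_train: np.ndarray, y_train, spec: ModelSpec):
    """Fit the classifier named by ``spec`` on finite feature vectors."""
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    if X.size == 0 or y.size == 0:
        raise ValueError("empty training set")
    if not np.all(np.isfinite(X)):
        raise ValueError("training vectors contain non-finite values (flagged epochs?)")
    if len(set(y.tolist())) < 2:
        raise ValueError("training set contains a single class")
    model = spec.build()
    model.fit(X, y)
    return model


@dataclass
class EvalReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    confusion: np.ndarray
    classes: list
    per_class: dict

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def evaluate_model(model, X_test: np.ndarray, y_test) -> EvalReport:
    """Confusion matrix plus accuracy and macro-averaged P/R/F1."""
    X = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test)
    if X.size == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(X)
    classes = sorted(set(y.tolist()) | set(y_pred.tolist()), key=str)
    cm = confusion_matrix(y, y_pred, labels=classes)
    accuracy = float(np.trace(cm) / cm.sum())
    p, r, f1, support = precision_recall_fscore_support(
        y, y_pred, labels=classes, average=None, zero_division=0
    )
    per_class = {
        str(c): {
            "precision": float(p[i]),
            "recall": float(r[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
        for i, c in enumerate(classes)
    }
    return EvalReport(
        accuracy=accuracy,
        precision_macro=float(p.mean()),
        recall_macro=float(r.mean()),
        f1_macro=float(f1.mean()),
        confusion=cm,
        classes=list(classes),
        per_class=per_class,
    )
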
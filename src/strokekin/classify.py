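"""Stroke-phase classification from scattering features.

Five standard classifiers (SVM, logistic regression, decision tree, KNN,
random forest) are compared on the four-class problem entry / pull / exit /
recovery.  Features are standardized inside each model pipeline (fitted on
the training split only); evaluation reports accuracy, macro precision /
recall / F1 and one-vs-rest macro ROC and precision-recall AUCs plus the
confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler, label_binarize
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .stroke import PHASES, UNLABELED

__all__ = [
    "MODEL_NAMES",
    "LabeledWindows",
    "ClassifierReport",
    "label_windows",
    "split_train_test",
    "make_models",
    "train_models",
    "evaluate",
    "compare_classifiers",
]

MODEL_NAMES = ("svm", "logistic_regression", "decision_tree", "knn",
               "random_forest")


@dataclass
class LabeledWindows:
    features: np.ndarray          # (n_windows, n_features)
    labels: np.ndarray            # (n_windows,) int codes into PHASES
    starts: np.ndarray            # window start sample indices
    sides: np.ndarray             # window provenance ("left"/"right")

    def __post_init__(self) -> None:
        n = len(self.features)
        if not (len(self.labels) == len(self.starts) == len(self.sides) == n):
            raise ValueError("features, labels, starts, sides must have "
                             "equal row counts")

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class ClassifierReport:
    model: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float | None
    prc_auc: float | None
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.roc_auc,
            "auc_prc": self.prc_auc,
            "confusion": self.confusion.tolist(),
        }


def majority_label(window_labels: np.ndarray) -> int:
    """Majority phase code in a window; ties break toward the phase that
    comes earlier in the cycle order entry < pull < exit < recovery."""
    w = np.asarray(window_labels)
    if np.any(w == UNLABELED):
        raise ValueError("window overlaps unlabeled samples")
    counts = np.bincount(w, minlength=len(PHASES))
    return int(np.argmax(counts))  # argmax returns the first (earliest) max


def label_windows(features: np.ndarray, starts: np.ndarray,
                  size: int, truth_labels: np.ndarray,
                  side: str) -> LabeledWindows:
    """Label feature rows by the majority ground-truth phase in each window."""
    features = np.asarray(features, dtype=float)
    starts = np.asarray(starts, dtype=int)
    if len(features) != len(starts):
        raise ValueError("features and starts must have equal row counts")
    if len(truth_labels) < (starts[-1] + size if len(starts) else 0):
        raise ValueError("truth labels do not cover every window span")
    labels = np.array(
        [majority_label(truth_labels[s:s + size]) for s in starts], dtype=int)
    return LabeledWindows(
        features=features, labels=labels, starts=starts,
        sides=np.full(len(starts), side, dtype=object),
    )


def concat_windows(parts: list[LabeledWindows]) -> LabeledWindows:
    return LabeledWindows(
        features=np.vstack([p.features for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        starts=np.concatenate([p.starts for p in parts]),
        sides=np.concatenate([p.sides for p in parts]),
    )


def split_train_test(data: LabeledWindows, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[LabeledWindows, LabeledWindows]:
    """Deterministic stratified split into disjoint train/test sets."""
    classes, counts = np.unique(data.labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 windows to stratify")
    idx_train, idx_test = train_test_split(
        np.arange(len(data)), train_size=train_fraction,
        stratify=data.labels, random_state=seed,
    )
    def take(idx):
        return LabeledWindows(
            features=data.features[idx], labels=data.labels[idx],
            starts=data.starts[idx], sides=data.sides[idx],
        )
    return take(idx_train), take(idx_test)


def make_models(seed: int = 0, n_trees: int = 100, knn_k: int = 5,
                svm_c: float = 10.0) -> dict[str, Pipeline]:
    """The five comparison models, each behind a train-fitted standardizer."""
    def pipe(est):
        return Pipeline([("scale", StandardScaler()), ("clf", est)])

    return {
        "svm": pipe(SVC(C=svm_c, kernel="rbf", random_state=seed)),
        "logistic_regression": pipe(
            LogisticRegression(max_iter=2000, random_state=seed)),
        "decision_tree": pipe(DecisionTreeClassifier(random_state=seed)),
        "knn": pipe(KNeighborsClassifier(n_neighbors=knn_k)),
        "random_forest": pipe(
            RandomForestClassifier(n_estimators=n_trees, random_state=seed)),
    }


def train_models(train: LabeledWindows,
                 models: dict[str, Pipeline] | None = None,
                 seed: int = 0) -> dict[str, Pipeline]:
    if models is None:
        models = make_models(seed=seed)
    if np.all(np.std(train.features, axis=0) == 0):
        raise ValueError("degenerate features: zero variance everywhere")
    for model in models.values():
        model.fit(train.features, train.labels)
    return models


def evaluate(name: str, model: Pipeline, test: LabeledWindows) -> ClassifierReport:
    if len(test) == 0:
        raise ValueError("test set is empty")
    present = np.unique(test.labels)
    if len(present) < 2:
        raise ValueError("test set must contain at least 2 classes")
    pred = model.predict(test.features)
    acc = accuracy_score(test.labels, pred)
    prec = precision_score(test.labels, pred, average="macro",
                           zero_division=0)
    rec = recall_score(test.labels, pred, average="macro", zero_division=0)
    f1 = f1_score(test.labels, pred, average="macro", zero_division=0)
    roc = prc = None
    scores = None
    if hasattr(model, "predict_proba"):
        scores = model.predict_proba(test.features)
    elif hasattr(model, "decision_function"):
        margins = model.decision_function(test.features)
        if margins.ndim == 1:
            margins = np.column_stack([-margins, margins])
        margins = margins - margins.max(axis=1, keepdims=True)
        e = np.exp(margins)
        scores = e / e.sum(axis=1, keepdims=True)
    if scores is not None:
        classes = model.classes_
        y_bin = label_binarize(test.labels, classes=classes)
        roc = float(roc_auc_score(test.labels, scores, multi_class="ovr",
                                  average="macro", labels=classes))
        prc = float(average_precision_score(y_bin, scores, average="macro"))
    conf = confusion_matrix(test.labels, pred,
                            labels=np.arange(len(PHASES)))
    return ClassifierReport(
        model=name, accuracy=float(acc), precision=float(prec),
        recall=float(rec), f1=float(f1), roc_auc=roc, prc_auc=prc,
        confusion=conf,
    )


def compare_classifiers(data: LabeledWindows, train_fraction: float = 0.8,
                        seed: int = 0) -> dict[str, ClassifierReport]:
    """80/20 stratified split, train all five models, evaluate each."""
    train, test = split_train_test(data, train_fraction, seed)
    models = train_models(train, seed=seed)
    return {name: evaluate(name, model, test)
            for name, model in models.items()}
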
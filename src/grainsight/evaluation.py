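"""Multi-classifier evaluation harness.

Trains a panel of eleven named classifiers (three SVM kernels, two k-NN
variants, linear discriminant analysis, and five multilayer-perceptron
sizes following the MATLAB Classification Learner naming convention) on a
stratified 50:50 holdout split, and reports per-classifier macro recall,
precision, F1, false-negative rate, accuracy (all in percent) plus wall
time and the confusion matrix.  k-fold cross-validated prediction is
available as an alternative protocol.

Macro averaging is the appropriate summary for class-balanced data; with
it the false-negative rate is exactly 100 minus macro recall, and F1 is
the harmonic mean of macro recall and macro precision — identities the
metric code preserves and the tests audit.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "EvalConfig",
    "MetricsRow",
    "DEFAULT_PANEL",
    "FULL_PANEL",
    "make_classifier",
    "split_holdout",
    "compute_metrics",
    "evaluate_panel",
]

# MATLAB-style hidden sizes: narrow=10, medium=25, wide=100
_NN_SIZES = {
    "narrow_nn": (10,),
    "medium_nn": (25,),
    "wide_nn": (100,),
    "bilayer_nn": (10, 10),
    "trilayer_nn": (10, 10, 10),
}

DEFAULT_PANEL = [
    "linear_svm",
    "quadratic_svm",
    "weighted_knn",
    "cosine_knn",
    "linear_discriminant",
    "medium_nn",
    "narrow_nn",
    "wide_nn",
    "bilayer_nn",
    "trilayer_nn",
]
# cubic SVM joins only in the post-selection experiment's panel
FULL_PANEL = DEFAULT_PANEL[:2] + ["cubic_svm"] + DEFAULT_PANEL[2:]


@dataclass(frozen=True)
class ClassifierSpec:
    name: str

    def __post_init__(self) -> None:
        if self.name not in FULL_PANEL:
            raise ValueError(f"unknown classifier {self.name!r}")


@dataclass(frozen=True)
class EvalConfig:
    split: float = 0.5
    cv_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split < 1:
            raise ValueError("split must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class MetricsRow:
    classifier: str
    recall: float
    precision: float
    f1: float
    fnr: float
    accuracy: float
    time_sec: float = 0.0

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "fnr": self.fnr,
            "accuracy": self.accuracy,
            "time_sec": self.time_sec,
        }


def make_classifier(name: str, seed: int = 0):
    """Instantiate one panel member behind a standardizing pipeline."""
    if name == "linear_svm":
        clf = SVC(kernel="linear", C=1.0)
    elif name == "quadratic_svm":
        # coef0=1 gives the inhomogeneous (1 + <x,y>)^d kernel, matching
        # the usual "quadratic/cubic SVM" presets
        clf = SVC(kernel="poly", degree=2, coef0=1.0, C=1.0)
    elif name == "cubic_svm":
        clf = SVC(kernel="poly", degree=3, coef0=1.0, C=1.0)
    elif name == "weighted_knn":
        clf = KNeighborsClassifier(n_neighbors=10, weights="distance")
    elif name == "cosine_knn":
        clf = KNeighborsClassifier(n_neighbors=10, metric="cosine")
    elif name == "linear_discriminant":
        clf = LinearDiscriminantAnalysis()
    elif name in _NN_SIZES:
        clf = MLPClassifier(
            hidden_layer_sizes=_NN_SIZES[name], activation="relu",
            max_iter=1000, random_state=seed,
        )
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return make_pipeline(StandardScaler(), clf)


def split_holdout(
    features: pd.DataFrame | np.ndarray, labels: np.ndarray, cfg: EvalConfig
):
    """Stratified, seeded, disjoint train/test split."""
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if (counts[counts > 0] < 2).any():
        raise ValueError("every class needs at least 2 samples to stratify")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=cfg.split,
        stratify=labels if cfg.stratified else None,
        random_state=cfg.seed,
    )
    return np.sort(train_idx), np.sort(test_idx)


def compute_metrics(cm: np.ndarray, classifier: str = "", time_sec: float = 0.0) -> MetricsRow:
    """Macro metrics (percent) from a confusion matrix (rows = true class).

    Classes absent from the test set are excluded from the macro averages
    with a warning; F1 is the harmonic mean of the macro recall and macro
    precision, and FNR = 100 - macro recall.
    """
    cm = np.asarray(cm, dtype=float)
    row_sums = cm.sum(axis=1)
    col_sums = cm.sum(axis=0)
    present = row_sums > 0
    if not present.all():
        warnings.warn("classes absent from the test set excluded from macro averages")
    diag = np.diag(cm)
    recall = 100.0 * np.mean(diag[present] / row_sums[present])
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class_prec = np.where(col_sums > 0, diag / np.where(col_sums > 0, col_sums, 1), 0.0)
    precision = 100.0 * np.mean(per_class_prec[present])
    f1 = 2 * recall * precision / (recall + precision) if recall + precision > 0 else 0.0
    accuracy = 100.0 * diag.sum() / cm.sum()
    return MetricsRow(
        classifier=classifier,
        recall=recall,
        precision=precision,
        f1=f1,
        fnr=100.0 - recall,
        accuracy=accuracy,
        time_sec=time_sec,
    )


def evaluate_panel(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    specs: list[str] | None = None,
    cfg: EvalConfig | None = None,
    use_cv: bool = False,
) -> list[tuple[MetricsRow, np.ndarray]]:
    """Fit and score every panel member; returns (metrics, confusion) pairs.

    Default protocol is the stratified 50:50 holdout; ``use_cv=True``
    switches to k-fold cross-validated prediction over all samples.
    """
    cfg = cfg or EvalConfig()
    specs = specs or DEFAULT_PANEL
    X = features.to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to evaluate")
    n_classes = int(y.max()) + 1

    results = []
    for name in specs:
        clf = make_classifier(name, seed=cfg.seed)
        t0 = time.perf_counter()
        if use_cv:
            skf = StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed)
            pred = cross_val_predict(clf, X, y, cv=skf)
            cm = _sk_confusion(y, pred, labels=np.arange(n_classes))
        else:
            train_idx, test_idx = split_holdout(X, y, cfg)
            clf.fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
            cm = _sk_confusion(y[test_idx], pred, labels=np.arange(n_classes))
        elapsed = time.perf_counter() - t0
        results.append((compute_metrics(cm, classifier=name, time_sec=elapsed), cm))
    return results


def results_frame(results: list[tuple[MetricsRow, np.ndarray]]) -> pd.DataFrame:
    """Panel results as a table with the standard column order."""
    return pd.DataFrame([m.as_dict() for m, _ in results]).set_index("classifier")
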
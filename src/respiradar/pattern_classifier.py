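"""Breathing-pattern classification: one-vs-one SVM (G-SVM) and KNN.

The four-class problem (normal, slow/deep, quick, meningitic) is solved by
six binary soft-margin SVMs voting one-vs-one; each binary machine solves
the dual problem, so the trained multipliers can be checked against the
KKT conditions (a_i >= 0, sum a_i y_i = 0, margin violations only at the
C bound).  A K-nearest-neighbours classifier serves as the baseline.
Evaluation follows a stratified fivefold cross-validation protocol (4:1
train:test per fold).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "LabeledDataset",
    "SvmModel",
    "KnnModel",
    "EvaluationReport",
    "train_svm",
    "train_knn",
    "crossvalidate",
    "featurize_cubes",
    "evaluate_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """Feature matrix with class labels and generation provenance."""

    features: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be (n, d) with one label per row")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class EvaluationReport:
    """Cross-validation outcome: accuracies and 4 x 4 confusion matrix."""

    classes: list[str]
    fold_accuracies: list[float]
    confusion: np.ndarray             # rows: true class, cols: predicted

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        rows = self.confusion.sum(axis=1)
        return {c: float(self.confusion[i, i] / rows[i]) if rows[i] else float("nan")
                for i, c in enumerate(self.classes)}

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion_matrix": self.confusion.tolist(),
        }


# ---------------------------------------------------------------------------
# SVM (one-vs-one)
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    """One-vs-one ensemble of binary soft-margin SVMs."""

    classes: list
    machines: dict              # (class_a, class_b) -> fitted binary SVC
    kernel: str
    C: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = len(x)
        votes = np.zeros((n, len(self.classes)))
        margin = np.zeros((n, len(self.classes)))
        index = {c: i for i, c in enumerate(self.classes)}
        for (ca, cb), clf in self.machines.items():
            dec = clf.decision_function(x)       # >0 -> second class of clf.classes_
            lo, hi = clf.classes_
            winners = np.where(dec > 0, index[hi], index[lo])
            votes[np.arange(n), winners] += 1
            margin[:, index[hi]] += np.abs(dec) * (dec > 0)
            margin[:, index[lo]] += np.abs(dec) * (dec <= 0)
        # ties broken by accumulated decision-function confidence
        out = []
        for i in range(n):
            tied = np.nonzero(votes[i] == votes[i].max())[0]
            best = tied[np.argmax(margin[i, tied])]
            out.append(self.classes[best])
        return np.asarray(out)

    def kkt_report(self) -> dict:
        """Dual-feasibility diagnostics per binary machine.

        For each class pair: ``sum_alpha_y`` (should be 0), the range of
        the multipliers ``alpha_i = |dual coefficient|`` (should lie in
        [0, C]), and the worst complementary-slackness residual over the
        *free* support vectors (those with ``alpha_i < C``), for which
        ``y_i f(x_i) = 1`` must hold.
        """
        report = {}
        for pair, clf in self.machines.items():
            coef = clf.dual_coef_.ravel()        # = alpha_i * y_i
            alphas = np.abs(coef)
            sv = clf.support_vectors_
            y = np.sign(coef)
            f = clf.decision_function(sv)
            free = alphas < self.C * (1 - 1e-8)
            slack = np.max(np.abs(y[free] * f[free] - 1.0)) if free.any() else 0.0
            report[pair] = {
                "sum_alpha_y": float(coef.sum()),
                "alpha_min": float(alphas.min()),
                "alpha_max": float(alphas.max()),
                "n_support": int(len(alphas)),
                "max_free_sv_slack": float(slack),
            }
        return report


def train_svm(data: LabeledDataset, kernel: str = "linear",
              C: float = 1.0) -> SvmModel:
    """Train the one-vs-one SVM ensemble (6 machines for 4 classes)."""
    classes = list(data.classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(data.labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    machines = {}
    for ca, cb in itertools.combinations(classes, 2):
        mask = (data.labels == ca) | (data.labels == cb)
        clf = SVC(kernel=kernel, C=C)
        clf.fit(data.features[mask], data.labels[mask])
        machines[(ca, cb)] = clf
    return SvmModel(classes=classes, machines=machines, kernel=kernel, C=C)


# ---------------------------------------------------------------------------
# KNN baseline
# ---------------------------------------------------------------------------

@dataclass
class KnnModel:
    """K-nearest-neighbours by Euclidean distance.

    Majority vote among the k nearest training points; vote ties break to
    the class of the single nearest neighbour among the tied classes.
    """

    features: np.ndarray
    labels: np.ndarray
    k: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        dist = cdist(x, self.features)
        order = np.argsort(dist, axis=1, kind="stable")[:, :self.k]
        out = []
        for row in order:
            neigh = self.labels[row]
            values, counts = np.unique(neigh, return_counts=True)
            tied = values[counts == counts.max()]
            if len(tied) == 1:
                out.append(tied[0])
            else:
                nearest_in_tie = next(lab for lab in neigh if lab in tied)
                out.append(nearest_in_tie)
        return np.asarray(out)


def train_knn(data: LabeledDataset, k: int = 5) -> KnnModel:
    if not 1 <= k <= len(data.labels):
        raise ValueError("k must satisfy 1 <= k <= n_samples")
    return KnnModel(features=data.features.copy(), labels=data.labels.copy(), k=k)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def crossvalidate(data: LabeledDataset, model_factory, n_folds: int = 5,
                  seed: int = 0) -> EvaluationReport:
    """Stratified k-fold evaluation.

    ``model_factory`` maps a training :class:`LabeledDataset` to a fitted
    model with ``predict``.  Folds are stratified by class with a seeded
    shuffle, so per-class fold sizes differ by at most one.
    """
    classes = list(data.classes)
    counts = {c: int(np.sum(data.labels == c)) for c in classes}
    if min(counts.values()) < n_folds:
        raise ValueError(f"every class needs >= {n_folds} samples, got {counts}")
    index = {c: i for i, c in enumerate(classes)}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc = []
    for train_idx, test_idx in skf.split(data.features, data.labels):
        model = model_factory(LabeledDataset(data.features[train_idx],
                                             data.labels[train_idx]))
        pred = model.predict(data.features[test_idx])
        truth = data.labels[test_idx]
        fold_acc.append(float(np.mean(pred == truth)))
        for t, p in zip(truth, pred):
            confusion[index[t], index[p]] += 1
    return EvaluationReport(classes=[str(c) for c in classes],
                            fold_accuracies=fold_acc, confusion=confusion)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def featurize_cubes(cubes, labels=None, **extract_kwargs) -> np.ndarray:
    """IF cubes -> HOG descriptors via the full waveform chain."""
    from .breath_metrics import normalize
    from .vitals_dsp import extract_respiration
    from .waveform_features import hog, render_image

    rows = []
    for cube in cubes:
        wave = extract_respiration(cube, **extract_kwargs)
        image = render_image(normalize(wave))
        rows.append(hog(image).vector)
    return np.asarray(rows)


def evaluate_pipeline(cubes, labels, *, classifier: str = "svm",
                      kernel: str = "linear", C: float = 1.0, k: int = 5,
                      n_folds: int = 5, seed: int = 0,
                      n_components: int | None = None,
                      variance_target: float = 0.95,
                      features: np.ndarray | None = None,
                      **extract_kwargs) -> EvaluationReport:
    """Full chain: extraction -> rendering -> HOG -> PCA -> cross-validation.

    ``features`` can carry precomputed HOG descriptors to reuse the
    expensive front-end across classifier comparisons.
    """
    from .waveform_features import fit_pca, project

    if features is None:
        features = featurize_cubes(cubes, **extract_kwargs)
    model = fit_pca(features, n_components=n_components,
                    variance_target=variance_target)
    reduced = project(model, features)
    data = LabeledDataset(reduced, np.asarray(labels),
                          provenance={"n_components": model.components.shape[0]})
    if classifier == "svm":
        factory = lambda d: train_svm(d, kernel=kernel, C=C)
    elif classifier == "knn":
        factory = lambda d: train_knn(d, k=k)
    else:
        raise ValueError("classifier must be 'svm' or 'knn'")
    return crossvalidate(data, factory, n_folds=n_folds, seed=seed)
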
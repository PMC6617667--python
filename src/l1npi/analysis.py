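"""Linear readout of descriptor space: SVM classification and PCA.

A linear support-vector machine on flattened L1NPI vectors tests whether two
ensembles are structurally distinguishable; because the classifier is linear,
its weight vector lives in the same space as the descriptors and can be
un-flattened into a *separating-hyperplane image*. Pixels of that image may
be negative, and it is the absolute pixel value that measures a pixel's
importance to the classification. PCA projections of descriptor space expose
trends (system size, potential parameter) as ordered scores.

Descriptors enter both procedures raw — they are already normalised masses —
so hyperplane and component images stay interpretable in L1NPI units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .descriptor import DescriptorVector, unflatten
from .image import ImageGrid

__all__ = [
    "ClassificationReport",
    "HyperplaneImage",
    "PCAProjection",
    "LinearSVMClassifier",
    "fit_linear_svm",
    "evaluate",
    "hyperplane_image",
    "pca_project",
    "stratified_split",
]


@dataclass(frozen=True)
class ClassificationReport:
    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = true, columns = predicted
    accuracy: float
    per_class_accuracy: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_accuracy": list(self.per_class_accuracy),
        }


@dataclass(frozen=True)
class HyperplaneImage:
    """SVM weight vector reshaped to the image grid; signed pixels."""

    grid: ImageGrid
    pixels: np.ndarray
    class_pair: tuple[str, str]

    @property
    def importance(self) -> np.ndarray:
        return np.abs(self.pixels)


@dataclass(frozen=True)
class PCAProjection:
    scores: np.ndarray  # (n, k)
    explained_variance: tuple[float, ...]
    components: np.ndarray  # (k, n_features), orthonormal
    mean: np.ndarray

    def component_image(self, i: int, grid: ImageGrid) -> np.ndarray:
        return unflatten(self.components[i], grid)


@dataclass
class LinearSVMClassifier:
    """One-vs-rest linear SVM over flattened descriptors."""

    model: OneVsRestClassifier
    classes: tuple[str, ...]
    c_reg: float
    seed: int
    n_features: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(x, dtype=float))

    def weight_vector(self, class_label: str) -> np.ndarray:
        """One-vs-rest hyperplane normal for ``class_label`` (positive side
        favours the class)."""
        if class_label not in self.classes:
            raise ValueError(f"unknown class {class_label!r}")
        if len(self.classes) == 2:
            # a single binary estimator, oriented towards classes[1]
            w = np.asarray(self.model.estimators_[0].coef_).ravel()
            return w if class_label == self.classes[1] else -w
        i = self.classes.index(class_label)
        return np.asarray(self.model.estimators_[i].coef_).ravel()


def _as_matrix(
    descriptors: list[DescriptorVector] | np.ndarray,
    labels: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(descriptors, np.ndarray):
        if labels is None:
            raise ValueError("labels required with a raw matrix")
        return np.asarray(descriptors, dtype=float), np.asarray(labels)
    x = np.vstack([d.values for d in descriptors])
    y = np.array([d.label for d in descriptors])
    return x, y


def fit_linear_svm(
    train: list[DescriptorVector] | np.ndarray,
    labels: list[str] | None = None,
    c_reg: float = 1.0,
    seed: int = 0,
) -> LinearSVMClassifier:
    """Fit a linear SVM (no kernel; one-vs-rest for k > 2 classes).

    ``c_reg`` is the usual soft-margin penalty C (default 1.0). Deterministic
    given the seed.
    """
    if c_reg <= 0:
        raise ValueError("c_reg must be positive")
    x, y = _as_matrix(train, labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    model = OneVsRestClassifier(SVC(kernel="linear", C=c_reg, random_state=seed))
    model.fit(x, y)
    return LinearSVMClassifier(
        model=model,
        classes=tuple(str(c) for c in model.classes_),
        c_reg=c_reg,
        seed=seed,
        n_features=x.shape[1],
    )


def evaluate(
    classifier: LinearSVMClassifier,
    test: list[DescriptorVector] | np.ndarray,
    labels: list[str] | None = None,
) -> ClassificationReport:
    """Confusion matrix (rows = true class) and overall/per-class accuracy."""
    x, y = _as_matrix(test, labels)
    unseen = set(np.unique(y)) - set(classifier.classes)
    if unseen:
        raise ValueError(f"test set contains unseen label(s): {sorted(unseen)}")
    pred = classifier.predict(x)
    conf = confusion_matrix(y, pred, labels=list(classifier.classes))
    total = conf.sum()
    row_sums = conf.sum(axis=1)
    per_class = tuple(
        float(conf[i, i] / row_sums[i]) if row_sums[i] else float("nan")
        for i in range(len(classifier.classes))
    )
    return ClassificationReport(
        classes=classifier.classes,
        confusion=conf,
        accuracy=float(np.trace(conf) / total),
        per_class_accuracy=per_class,
    )


def hyperplane_image(
    classifier: LinearSVMClassifier, class_label: str, grid: ImageGrid
) -> HyperplaneImage:
    """Un-flatten the one-vs-rest weight vector of ``class_label``.

    Positive pixels favour the class, negative pixels the rest; absolute
    value encodes importance.
    """
    w = classifier.weight_vector(class_label)
    if len(classifier.classes) == 2:
        other = next(c for c in classifier.classes if c != class_label)
    else:
        other = "rest"
    return HyperplaneImage(grid, unflatten(w, grid), (class_label, other))


def pca_project(
    descriptors: list[DescriptorVector] | np.ndarray,
    n_components: int = 2,
) -> PCAProjection:
    """Mean-centred PCA of the descriptor matrix.

    Each component's sign is fixed so its largest-magnitude loading is
    positive — a deterministic convention across platforms.
    """
    if isinstance(descriptors, np.ndarray):
        x = np.asarray(descriptors, dtype=float)
    else:
        x = np.vstack([d.values for d in descriptors])
    if x.shape[0] <= n_components:
        raise ValueError(
            f"need more than {n_components} samples, got {x.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    components = pca.components_.copy()
    for i in range(n_components):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    return PCAProjection(
        scores=scores,
        explained_variance=tuple(float(v) for v in pca.explained_variance_ratio_),
        components=components,
        mean=pca.mean_,
    )


def stratified_split(
    descriptors: list[DescriptorVector],
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[list[DescriptorVector], list[DescriptorVector]]:
    """Stratified train/test split (default 70/30) with a fixed seed."""
    labels = [d.label for d in descriptors]
    idx_train, idx_test = train_test_split(
        np.arange(len(descriptors)),
        test_size=test_fraction,
        random_state=seed,
        stratify=labels,
    )
    return (
        [descriptors[i] for i in idx_train],
        [descriptors[i] for i in idx_test],
    )
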
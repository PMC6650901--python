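"""Pixel-wise labeling of (segmented) cubes and map-accuracy metrics.

The automaton only homogenizes spectra; turning the smoothed cube into a
class map is delegated to any pixel-wise classifier.  Two are provided behind
one interface: an RBF-kernel one-vs-one SVM (scikit-learn ``SVC``, with an
optional stratified cross-validated grid search over C and gamma) and a
dependency-light nearest-centroid classifier under spectral-angle distance.

Accuracy of a predicted map against ground truth is summarized by the usual
remote-sensing metrics — overall accuracy (OA), average accuracy (AA, mean
per-class recall) and the chance-corrected kappa coefficient — all reported
as percentages, evaluated on labeled pixels excluding the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .core import LabelMap, SpectralImage, spectral_angle_maps

__all__ = [
    "ClassifierSpec",
    "AccuracyReport",
    "split_train_test",
    "classify_pixels",
    "accuracy",
]

_DEFAULT_C_GRID = (1.0, 10.0, 100.0, 1000.0)
_DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class ClassifierSpec:
    """Which classifier to fit and how.

    kind : 'svm' (one-vs-one RBF SVC) or 'centroid' (nearest class-mean
        spectrum under spectral angle).
    C, gamma : fixed SVM hyperparameters; when None a stratified
        ``cv_folds``-fold cross-validated grid search picks them.
    """

    kind: str = "svm"
    C: float | None = None
    gamma: float | None = None
    cv_folds: int = 5
    C_grid: tuple = _DEFAULT_C_GRID
    gamma_grid: tuple = _DEFAULT_GAMMA_GRID
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "centroid"):
            raise ValueError("kind must be 'svm' or 'centroid'")


@dataclass
class AccuracyReport:
    """OA/AA/kappa (percent), per-class accuracies and the confusion matrix."""

    oa: float
    aa: float
    kappa: float
    per_class: dict[int, float]
    confusion: np.ndarray
    classes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": int(k), "accuracy_pct": v} for k, v in self.per_class.items()]
        rows.append({"class": "OA", "accuracy_pct": self.oa})
        rows.append({"class": "AA", "accuracy_pct": self.aa})
        rows.append({"class": "kappa", "accuracy_pct": self.kappa})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "OA": self.oa,
            "AA": self.aa,
            "kappa": self.kappa,
            "per_class": {int(k): v for k, v in self.per_class.items()},
        }


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def split_train_test(
    labels: LabelMap,
    per_class: int | None = None,
    fraction: float | None = None,
    total: int | None = None,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified selection of training pixels; the rest are the test pool.

    Exactly one of ``per_class`` (count per class), ``fraction`` (of each
    class) or ``total`` (overall budget, split proportionally to class sizes,
    at least one per class) must be given.  A class smaller than the request
    contributes all but one pixel (with a warning); single-pixel classes are
    excluded entirely.

    Returns flat pixel index arrays ``(train, test)``.
    """
    given = sum(x is not None for x in (per_class, fraction, total))
    if given != 1:
        raise ValueError("give exactly one of per_class, fraction, total")
    rng = np.random.default_rng(seed)
    flat = labels.labels.ravel()
    classes = labels.class_ids()

    sizes = {int(k): int((flat == k).sum()) for k in classes}
    wanted: dict[int, int] = {}
    if per_class is not None:
        wanted = {k: per_class for k in sizes}
    elif fraction is not None:
        wanted = {k: max(1, round(fraction * n)) for k, n in sizes.items()}
    else:
        grand = sum(sizes.values())
        wanted = {k: max(1, round(total * n / grand)) for k, n in sizes.items()}

    train_parts, test_parts = [], []
    for k in sorted(sizes):
        idx = np.flatnonzero(flat == k)
        if idx.size <= 1:
            warnings.warn(f"class {k} has {idx.size} pixel(s); excluded from split")
            continue
        n_req = wanted[k]
        if n_req >= idx.size:
            warnings.warn(
                f"class {k}: requested {n_req} training pixels of {idx.size}; "
                "taking all but one"
            )
            n_req = idx.size - 1
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_req])
        test_parts.append(perm[n_req:])
    if not train_parts:
        raise ValueError("no class is large enough to split")
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _fit_svm(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    if spec.C is not None and spec.gamma is not None:
        clf = SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)
        clf.fit(X, y)
        return clf
    min_count = min(np.unique(y, return_counts=True)[1])
    folds = max(2, min(spec.cv_folds, int(min_count)))
    grid = {"C": list(spec.C_grid), "gamma": list(spec.gamma_grid)}
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(SVC(kernel="rbf"), grid, cv=cv, n_jobs=None)
    search.fit(X, y)
    return search.best_estimator_


class _NearestCentroid:
    """Nearest class-mean spectrum under spectral-angle distance."""

    def fit(self, X: np.ndarray, y: np.ndarray):
        self.classes_ = np.unique(y)
        self.centroids_ = np.stack([X[y == k].mean(axis=0) for k in self.classes_])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = np.stack(
            [
                spectral_angle_maps(X, np.broadcast_to(c, X.shape))
                for c in self.centroids_
            ],
            axis=-1,
        )
        return self.classes_[np.argmin(d, axis=-1)]


def classify_pixels(
    img: SpectralImage,
    train_idx: np.ndarray,
    train_labels: np.ndarray | LabelMap,
    spec: ClassifierSpec | None = None,
) -> LabelMap:
    """Fit on the training pixels' spectra and label every pixel of the cube.

    ``train_labels`` may be a full label map (training labels read off at
    ``train_idx``, in the map's original label values) or an array aligned
    with ``train_idx``.
    """
    spec = spec or ClassifierSpec()
    spectra = img.data.reshape(-1, img.bands)
    if isinstance(train_labels, LabelMap):
        y = train_labels.raw.ravel()[train_idx]
    else:
        y = np.asarray(train_labels)
        if y.size != train_idx.size:
            y = y.ravel()[train_idx]
    X = spectra[train_idx]
    if y.size == 0:
        raise ValueError("training set is empty")
    if np.unique(y).size == 1:  # single class degenerates to a constant map
        pred = np.full(spectra.shape[0], y[0], dtype=int)
        return LabelMap(pred.reshape(img.data.shape[:2]))
    if spec.kind == "svm":
        clf = _fit_svm(X, y, spec)
    else:
        clf = _NearestCentroid().fit(X, y)
    pred = clf.predict(spectra)
    return LabelMap(pred.reshape(img.data.shape[:2]))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy(
    pred: LabelMap, truth: LabelMap, mask: np.ndarray | None = None
) -> AccuracyReport:
    """OA, AA, kappa and per-class accuracies, as percentages.

    ``mask`` (flat indices or boolean grid) restricts the evaluation, e.g. to
    labeled pixels outside the training set; by default all pixels count.
    """
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth differ in shape")
    # compare in original label values: canonicalization must not re-pair ids
    p = pred.raw.ravel()
    t = truth.raw.ravel()
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask.ravel())
        p = p[mask]
        t = t[mask]
    if p.size == 0:
        raise ValueError("empty evaluation mask")
    classes = np.unique(np.concatenate([t, p]))
    cm = confusion_matrix(t, p, labels=classes)
    oa = 100.0 * np.trace(cm) / cm.sum()
    recalls = {}
    for i, k in enumerate(classes):
        row = cm[i].sum()
        if row:
            recalls[int(k)] = 100.0 * cm[i, i] / row
    aa = float(np.mean(list(recalls.values())))
    kappa = 100.0 * cohen_kappa_score(t, p)
    return AccuracyReport(
        oa=float(oa),
        aa=aa,
        kappa=float(kappa),
        per_class=recalls,
        confusion=cm,
        classes=classes,
    )
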
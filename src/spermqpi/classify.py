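"""Feature extraction, dataset splitting and classification.

Two classification paths are provided over QC-retained phase maps:

* a classical path — 11 morphological and phase-texture features from
  the segmented head region fed to an SVM (RBF), Gaussian Naive Bayes or
  k-nearest-neighbour classifier;
* a CNN path (:mod:`spermqpi.cnn`) — a small convolutional network
  trained on cropped, resampled phase images with SGD-with-momentum,
  initial learning rate 1e-4, for 30 epochs.

Both report a 4×4 confusion matrix (rows = ground truth, columns =
predictions, class order ``normal, ethanol, h2o2, cryo``) with per-class
sensitivity, specificity and accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy import ndimage
from skimage.measure import label as sk_label, regionprops
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import CLASS_ORDER, ConfusionMatrix, PhaseMap, SplitSpec

__all__ = [
    "FEATURE_NAMES",
    "split_dataset",
    "segment_head",
    "extract_features",
    "features_from_maps",
    "train_classical",
    "confusion_metrics",
]

#: fixed feature order: head morphology in physical units, then phase texture
FEATURE_NAMES = (
    "area",  # µm²
    "perimeter",  # µm
    "major_axis",  # µm
    "minor_axis",  # µm
    "eccentricity",
    "circularity",
    "mean_phase",  # rad
    "max_phase",  # rad
    "phase_variance",  # rad²
    "phase_skewness",
    "phase_entropy",  # bits (32-bin histogram)
)


def split_dataset(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split.

    Per class, the test count is ``round((1 − train_fraction) · n)``
    (round half up), so 2,400 images at 70/30 give exactly 720 test
    images.  Returns ``(train_idx, test_idx)``, disjoint and exhaustive,
    deterministic given ``spec.seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    train, test = [], []
    classes = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 2:
            raise ValueError(f"class {cls!r} needs at least 2 samples")
        n_test = spec.test_count(idx.size)
        if n_test == 0 or n_test == idx.size:
            raise ValueError("split produces an empty partition for a class")
        perm = rng.permutation(idx) if spec.stratified else idx
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def segment_head(phase: PhaseMap) -> np.ndarray:
    """Segment the head: largest high-phase blob.

    Threshold at 50 % of the 99th-percentile phase (computed over
    positive pixels), morphological opening, then the largest 8-connected
    component.  Raises on an empty mask.
    """
    v = phase.values
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("cannot segment an empty phase map")
    thr = 0.5 * float(np.percentile(pos, 99))
    mask = v >= thr
    yy, xx = np.mgrid[-2:3, -2:3]
    mask = ndimage.binary_opening(mask, structure=xx * xx + yy * yy <= 4)
    lbl = sk_label(mask, connectivity=2)
    if lbl.max() == 0:
        raise ValueError("head segmentation produced an empty mask")
    sizes = np.bincount(lbl.ravel())[1:]
    return lbl == (1 + int(np.argmax(sizes)))


def extract_features(phase: PhaseMap, mask: np.ndarray) -> np.ndarray:
    """The 11-feature vector of the segmented head region.

    Geometric features are reported in physical units via the pixel
    pitch; texture features are computed on the phase values inside the
    mask.  Raises on a degenerate (< 8 px) mask.
    """
    if mask.sum() < 8:
        raise ValueError("degenerate head mask")
    pp = phase.pixel_pitch
    props = regionprops(mask.astype(int))[0]
    vals = phase.values[mask]
    area = props.area * pp * pp
    # Crofton estimator: much smaller bias than the chain-code perimeter on
    # smooth convex shapes, keeping circularity of a disk near 1
    perimeter = props.perimeter_crofton * pp
    if perimeter <= 0:
        raise ValueError("degenerate head mask (zero perimeter)")
    circularity = min(4.0 * np.pi * area / perimeter**2, 1.0)
    hist, _ = np.histogram(vals, bins=32)
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log2(p)).sum())
    var = float(np.var(vals))
    skew = float(stats.skew(vals)) if var > 1e-12 else 0.0
    feats = np.array(
        [
            area,
            perimeter,
            props.axis_major_length * pp,
            props.axis_minor_length * pp,
            props.eccentricity,
            circularity,
            float(vals.mean()),
            float(vals.max()),
            var,
            skew,
            entropy,
        ]
    )
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite feature value")
    return feats


def features_from_maps(maps: list[PhaseMap]) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and label array for a list of labelled phase maps."""
    X = np.stack([extract_features(pm, segment_head(pm)) for pm in maps])
    y = np.array([pm.meta["label"] for pm in maps])
    return X, y


def _make_model(model: str, seed: int):
    if model == "svm":
        clf = SVC(kernel="rbf", C=10.0, gamma="scale", random_state=seed & 0x7FFFFFFF)
    elif model == "naive_bayes":
        clf = GaussianNB()
    elif model == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    else:
        raise ValueError(f"unknown model {model!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    index = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts)


def train_classical(
    features: np.ndarray,
    labels: np.ndarray,
    model: str = "svm",
    spec: SplitSpec | None = None,
):
    """Fit a classical classifier on the train split; evaluate on the test split.

    Requires at least 10 samples per class.  Returns
    ``(fitted_pipeline, ConfusionMatrix)``.
    """
    spec = spec or SplitSpec()
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 10:
        raise ValueError("need >= 10 samples per class")
    unknown = set(classes) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    train_idx, test_idx = split_dataset(labels, spec)
    if len(np.unique(labels[train_idx])) < len(classes):
        raise ValueError("train split lost a class")
    pipe = _make_model(model, spec.seed)
    pipe.fit(features[train_idx], labels[train_idx])
    y_pred = pipe.predict(features[test_idx])
    return pipe, _confusion(labels[test_idx], y_pred)


def confusion_metrics(matrix: ConfusionMatrix) -> dict:
    """Per-class sensitivity, specificity, accuracy and macro averages.

    One-vs-rest: sensitivity = TP / (TP + FN), specificity =
    TN / (TN + FP), accuracy = (TP + TN) / total.  A class with no true
    instances gets an undefined (NaN) sensitivity, flagged and excluded
    from the macro average.
    """
    m = matrix.counts.astype(float)
    total = m.sum()
    per_class: dict[str, dict[str, float]] = {}
    undefined: list[str] = []
    for i, name in enumerate(matrix.class_names):
        tp = m[i, i]
        fn = m[i].sum() - tp
        fp = m[:, i].sum() - tp
        tn = total - tp - fn - fp
        row = m[i].sum()
        sens = tp / row if row > 0 else float("nan")
        if row == 0:
            undefined.append(name)
        spec_ = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
        acc = (tp + tn) / total
        per_class[name] = {
            "sensitivity": float(sens),
            "specificity": float(spec_),
            "accuracy": float(acc),
        }
    valid = [n for n in matrix.class_names if n not in undefined]
    macro = {
        key: float(np.mean([per_class[n][key] for n in valid]))
        for key in ("sensitivity", "specificity", "accuracy")
    }
    return {
        "per_class": per_class,
        "macro": macro,
        "matrix": matrix.counts.tolist(),
        "undefined_sensitivity": undefined,
        "overall_accuracy": float(np.trace(m) / total),
    }
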
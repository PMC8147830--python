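"""Three-class random-forest classification of middle-ear OCT A-scans.

The classifier maps each A-scan's feature vector (TM thickness, peak count,
attenuation coefficient) to one of three middle-ear states: normal, biofilm,
or effusion with biofilm. Around it this module implements the real-time
readout used on the acquisition device -- the most recent 250 post-trigger
A-scans feed a "line classification", the percentage of valid A-scans
assigned to each class -- and leave-one-ear-out cross-validation (one fold
per ear, so no subject contributes to both training and evaluation of any
fold).

Models are bagged decision-tree ensembles trained with scikit-learn but
persisted as a portable JSON bundle of flattened tree arrays; prediction
always runs from those arrays, so a saved and reloaded model is predictive
bit-for-bit identical to the freshly trained one. Majority-vote ties between
classes resolve by the fixed class order NORMAL < BIOFILM < EFFUSION_BIOFILM.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from numpy.random import SeedSequence

from .features import FeatureConfig, FeatureVector, extract_features
from .labels import ABNORMAL_CLASSES, PRIMARY_CLASSES, ClassLabel
from .phantom import LabeledAScan, MModeImage

#: the feature manifest every model is trained against, in column order
FEATURE_NAMES: tuple[str, ...] = (
    "tm_thickness_physical_um",
    "peak_count",
    "attenuation_mm1",
)

DEFAULT_WINDOW = 250


@dataclass(frozen=True)
class RandomForestParams:
    """Hyperparameters of the bagged-tree ensemble."""

    n_estimators: int = 100
    max_depth: int | None = None
    max_features: str | int | float = "sqrt"
    bootstrap: bool = True
    #: optional per-class weighting; None = unweighted (classes as sampled)
    class_weight: str | dict | None = None


def feature_matrix(fvs: Sequence[FeatureVector]) -> np.ndarray:
    """Stack valid feature vectors into the model's design matrix.

    A NaN attenuation on a valid A-scan means no measurable decay behind the
    TM and enters the matrix as 0.0; every other field of a valid vector is
    guaranteed present.
    """
    rows = []
    for fv in fvs:
        if not fv.valid:
            raise ValueError("feature_matrix only accepts valid feature vectors")
        mu = fv.attenuation_mm1
        rows.append(
            [
                fv.tm_thickness_physical_um,
                float(fv.peak_count),
                0.0 if math.isnan(mu) else mu,
            ]
        )
    return np.asarray(rows, dtype=np.float64).reshape(-1, len(FEATURE_NAMES))


def _seed_int(seed: int | SeedSequence, *key: int) -> int:
    """A 31-bit integer sub-seed derived from ``seed`` and a spawn key."""
    if isinstance(seed, SeedSequence):
        ss = SeedSequence(entropy=seed.entropy, spawn_key=tuple(key))
    else:
        ss = SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class _FlatTree:
    """A decision tree flattened to parallel arrays (scikit-learn layout)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    #: per-node class-count rows, normalised to probabilities at leaves
    value: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            left = self.children_left[node]
            split = left >= 0
            if not split.any():
                break
            rows = np.nonzero(split)[0]
            nodes = node[rows]
            go_left = X[rows, self.feature[nodes]] <= self.threshold[nodes]
            node[rows] = np.where(go_left, left[rows], self.children_right[nodes])
        counts = self.value[node]
        return counts / counts.sum(axis=1, keepdims=True)

    def to_dict(self) -> dict[str, list]:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_FlatTree":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            value=np.asarray(d["value"], dtype=np.float64),
        )


@dataclass
class ClassifierModel:
    """A trained, portable three-class A-scan classifier."""

    trees: list[_FlatTree]
    feature_names: tuple[str, ...]
    classes: tuple[ClassLabel, ...]
    params: RandomForestParams
    rng_seed: int
    #: sha256 of the training design matrix and labels
    training_fingerprint: str
    n_dropped_invalid: int = 0
    warnings_log: tuple[str, ...] = ()

    def check_manifest(self, feature_names: Sequence[str]) -> None:
        if tuple(feature_names) != tuple(self.feature_names):
            missing = set(self.feature_names) - set(feature_names)
            extra = set(feature_names) - set(self.feature_names)
            raise ValueError(
                f"feature manifest mismatch: missing={sorted(missing)}, "
                f"extra={sorted(extra)}"
            )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities over ``PRIMARY_CLASSES`` (ensemble average)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected (n, {len(self.feature_names)}) design matrix, "
                f"got {X.shape}"
            )
        proba = np.zeros((X.shape[0], len(self.classes)))
        for tree in self.trees:
            proba += tree.predict_proba(X)
        proba /= len(self.trees)
        # expand to the full primary-class simplex (zero for absent classes)
        full = np.zeros((X.shape[0], len(PRIMARY_CLASSES)))
        for j, cls in enumerate(self.classes):
            full[:, PRIMARY_CLASSES.index(cls)] = proba[:, j]
        return full

    def predict(self, X: np.ndarray) -> list[ClassLabel]:
        """Majority-vote labels; ties resolve toward the earlier primary class."""
        proba = self.predict_proba(X)
        return [PRIMARY_CLASSES[i] for i in np.argmax(proba, axis=1)]

    # ---- persistence ---------------------------------------------------
    def to_bundle(self) -> dict[str, Any]:
        return {
            "schema_version": "1",
            "kind": "earoct-random-forest",
            "feature_names": list(self.feature_names),
            "classes": [c.value for c in self.classes],
            "params": {
                "n_estimators": self.params.n_estimators,
                "max_depth": self.params.max_depth,
                "max_features": self.params.max_features,
                "bootstrap": self.params.bootstrap,
                "class_weight": self.params.class_weight,
            },
            "rng_seed": self.rng_seed,
            "training_fingerprint": self.training_fingerprint,
            "n_dropped_invalid": self.n_dropped_invalid,
            "warnings": list(self.warnings_log),
            "trees": [t.to_dict() for t in self.trees],
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_bundle()))
        return path

    @classmethod
    def from_bundle(cls, bundle: dict[str, Any]) -> "ClassifierModel":
        if bundle.get("kind") != "earoct-random-forest":
            raise ValueError("not an earoct random-forest model bundle")
        return cls(
            trees=[_FlatTree.from_dict(t) for t in bundle["trees"]],
            feature_names=tuple(bundle["feature_names"]),
            classes=tuple(ClassLabel(c) for c in bundle["classes"]),
            params=RandomForestParams(**bundle["params"]),
            rng_seed=int(bundle["rng_seed"]),
            training_fingerprint=bundle["training_fingerprint"],
            n_dropped_invalid=int(bundle.get("n_dropped_invalid", 0)),
            warnings_log=tuple(bundle.get("warnings", ())),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        return cls.from_bundle(json.loads(Path(path).read_text()))


def train_classifier(
    features: Sequence[FeatureVector],
    labels: Sequence[ClassLabel],
    params: RandomForestParams | None = None,
    rng_seed: int = 0,
) -> ClassifierModel:
    """Fit the random forest on valid feature vectors.

    Invalid vectors are dropped (their count is recorded on the model).
    Deterministic for a fixed seed. A single-class training set still yields
    a usable constant model, with a warning recorded on the bundle.
    """
    from sklearn.ensemble import RandomForestClassifier

    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    params = params or RandomForestParams()
    keep = [(fv, lab) for fv, lab in zip(features, labels) if fv.valid]
    n_dropped = len(features) - len(keep)
    if not keep:
        raise ValueError("no valid feature vectors to train on")
    X = feature_matrix([fv for fv, _ in keep])
    y = np.array([PRIMARY_CLASSES.index(lab) for _, lab in keep], dtype=np.int64)

    logs = []
    present = sorted(set(y.tolist()))
    if len(present) < 2:
        logs.append(
            f"single-class training set ({PRIMARY_CLASSES[present[0]].value}): "
            "the model will predict that class for any input"
        )

    forest = RandomForestClassifier(
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        max_features=params.max_features,
        bootstrap=params.bootstrap,
        class_weight=params.class_weight,
        random_state=_seed_int(rng_seed, 0),
        n_jobs=1,
    )
    forest.fit(X, y)

    trees = []
    for est in forest.estimators_:
        t = est.tree_
        trees.append(
            _FlatTree(
                children_left=t.children_left.copy(),
                children_right=t.children_right.copy(),
                feature=t.feature.copy(),
                threshold=t.threshold.copy(),
                value=t.value[:, 0, :].copy(),
            )
        )
    fingerprint = hashlib.sha256(X.tobytes() + y.tobytes()).hexdigest()
    return ClassifierModel(
        trees=trees,
        feature_names=FEATURE_NAMES,
        classes=tuple(PRIMARY_CLASSES[i] for i in forest.classes_),
        params=params,
        rng_seed=int(rng_seed) if isinstance(rng_seed, int) else 0,
        training_fingerprint=fingerprint,
        n_dropped_invalid=n_dropped,
        warnings_log=tuple(logs),
    )


def classify_ascans(
    model: ClassifierModel, features: Sequence[FeatureVector]
) -> list[ClassLabel]:
    """One label per feature vector; invalid inputs become ``INVALID``,
    never a guessed class."""
    model.check_manifest(FEATURE_NAMES)
    labels: list[ClassLabel] = [ClassLabel.INVALID] * len(features)
    valid_idx = [i for i, fv in enumerate(features) if fv.valid]
    if valid_idx:
        X = feature_matrix([features[i] for i in valid_idx])
        for i, lab in zip(valid_idx, model.predict(X)):
            labels[i] = lab
    return labels


def realtime_window(
    labels: Sequence[ClassLabel],
    trigger_index: int,
    window: int = DEFAULT_WINDOW,
) -> tuple[list[ClassLabel], bool]:
    """The labels feeding the real-time display.

    Of the A-scans at or after the trigger, the most recent ``window``
    (default 250) are returned. If fewer than ``window`` post-trigger labels
    exist, all of them are returned with the shortfall flag set.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (0 <= trigger_index < len(labels)):
        raise ValueError(
            f"trigger_index={trigger_index} outside the label sequence "
            f"[0, {len(labels)})"
        )
    post = list(labels[trigger_index:])
    if len(post) >= window:
        return post[-window:], False
    return post, True


@dataclass(frozen=True)
class LineClassification:
    """Percentage of valid A-scans per class (the 'line classification')."""

    percent: dict[ClassLabel, float]
    n_valid: int
    n_excluded: int
    empty: bool = False

    @property
    def abnormal_percent(self) -> float:
        if self.empty:
            return math.nan
        return sum(self.percent[c] for c in ABNORMAL_CLASSES)

    @property
    def dominant(self) -> ClassLabel | None:
        if self.empty:
            return None
        return max(PRIMARY_CLASSES, key=lambda c: (self.percent[c], -PRIMARY_CLASSES.index(c)))

    def to_dict(self) -> dict[str, Any]:
        return {
            "percent": {c.value: self.percent.get(c, math.nan) for c in PRIMARY_CLASSES},
            "abnormal_percent": self.abnormal_percent,
            "n_valid": self.n_valid,
            "n_excluded": self.n_excluded,
            "empty": self.empty,
        }


def line_classification(labels: Sequence[ClassLabel]) -> LineClassification:
    """Per-class percentages over the valid A-scans of a label sequence.

    ``INVALID`` labels are excluded from the denominator; with no valid
    labels at all the result is flagged empty (no percentages).
    """
    counts = Counter(labels)
    n_excluded = counts.pop(ClassLabel.INVALID, 0)
    n_valid = sum(counts.values())
    if n_valid == 0:
        return LineClassification(
            percent={c: math.nan for c in PRIMARY_CLASSES},
            n_valid=0,
            n_excluded=n_excluded,
            empty=True,
        )
    percent = {c: 100.0 * counts.get(c, 0) / n_valid for c in PRIMARY_CLASSES}
    return LineClassification(percent=percent, n_valid=n_valid, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# leave-one-ear-out cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldReport:
    ear_id: str
    n: int
    accuracy: float
    precision: dict[ClassLabel, float]
    recall: dict[ClassLabel, float]


@dataclass(frozen=True)
class CVReport:
    folds: tuple[FoldReport, ...]
    overall_accuracy: float
    #: rows = true class, columns = predicted class, order = PRIMARY_CLASSES
    confusion: np.ndarray
    n_total: int
    n_dropped_invalid: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class FeatureRecord:
    """One A-scan's features with its ear grouping and true class."""

    ear_id: str
    label: ClassLabel
    features: FeatureVector


def extract_dataset_features(
    dataset: Sequence[LabeledAScan], config: FeatureConfig = FeatureConfig()
) -> list[FeatureRecord]:
    return [
        FeatureRecord(rec.ear_id, rec.label, extract_features(rec.ascan, config))
        for rec in dataset
    ]


def loso_cv(
    records: Sequence[FeatureRecord],
    params: RandomForestParams | None = None,
    rng_seed: int = 0,
) -> CVReport:
    """Leave-one-ear-out cross-validation.

    One fold per distinct ear: the model is trained on every other ear's
    valid A-scans and evaluated on the held-out ear's valid A-scans, so no
    subject leaks between training and evaluation. Overall accuracy pools
    correct predictions over all folds.
    """
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    ears = list(dict.fromkeys(r.ear_id for r in records))
    if len(ears) < 2:
        raise ValueError("leave-one-ear-out requires at least 2 ears")
    valid = [r for r in records if r.features.valid]
    n_dropped = len(records) - len(valid)

    folds = []
    pooled_true: list[int] = []
    pooled_pred: list[int] = []
    label_ids = list(range(len(PRIMARY_CLASSES)))
    for f, ear in enumerate(ears):
        train = [r for r in valid if r.ear_id != ear]
        test = [r for r in valid if r.ear_id == ear]
        if not test:
            folds.append(
                FoldReport(ear_id=ear, n=0, accuracy=math.nan, precision={}, recall={})
            )
            continue
        model = train_classifier(
            [r.features for r in train],
            [r.label for r in train],
            params=params,
            rng_seed=_seed_int(rng_seed, 1, f),
        )
        y_true = [PRIMARY_CLASSES.index(r.label) for r in test]
        y_pred = [
            PRIMARY_CLASSES.index(lab)
            for lab in model.predict(feature_matrix([r.features for r in test]))
        ]
        pooled_true.extend(y_true)
        pooled_pred.extend(y_pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prec, rec, _, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=label_ids, zero_division=0.0
            )
        acc = float(np.mean(np.array(y_true) == np.array(y_pred)))
        folds.append(
            FoldReport(
                ear_id=ear,
                n=len(test),
                accuracy=acc,
                precision={c: float(p) for c, p in zip(PRIMARY_CLASSES, prec)},
                recall={c: float(r) for c, r in zip(PRIMARY_CLASSES, rec)},
            )
        )
    overall = float(np.mean(np.array(pooled_true) == np.array(pooled_pred)))
    conf = confusion_matrix(pooled_true, pooled_pred, labels=label_ids)
    return CVReport(
        folds=tuple(folds),
        overall_accuracy=overall,
        confusion=conf,
        n_total=len(pooled_true),
        n_dropped_invalid=n_dropped,
    )


# ---------------------------------------------------------------------------
# whole-image classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MModeClassification:
    """Both classifier readouts of one M-mode image."""

    labels: tuple[ClassLabel, ...]
    #: real-time readout: most recent `window` post-trigger A-scans
    windowed: LineClassification
    #: post-hoc readout: every A-scan of the scan, invalid ones excluded
    full_scan: LineClassification
    shortfall: bool
    window: int
    trigger_index: int


def classify_mmode(
    mmode: MModeImage,
    model: ClassifierModel,
    config: FeatureConfig = FeatureConfig(),
    window: int = DEFAULT_WINDOW,
) -> MModeClassification:
    """Classify every column of an M-mode image.

    Returns per-column labels plus the two line-classification readouts the
    device shows: the real-time one over the most recent ``window``
    post-trigger A-scans, and the post-processing one over the entire scan.
    An absent trigger index treats the whole scan as post-trigger.
    """
    if len(mmode) == 0:
        raise ValueError("empty M-mode image")
    fvs = [extract_features(a, config) for a in mmode.ascans]
    labels = classify_ascans(model, fvs)
    trigger = mmode.trigger_index if mmode.trigger_index is not None else 0
    window_labels, shortfall = realtime_window(labels, trigger, window)
    return MModeClassification(
        labels=tuple(labels),
        windowed=line_classification(window_labels),
        full_scan=line_classification(labels),
        shortfall=shortfall,
        window=window,
        trigger_index=trigger,
    )
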
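"""Training, evaluation, persistence and interpretation of state classifiers.

The classifier maps a pair-distance descriptor to the probability that the
conformation is active-like ("active" is the positive class throughout).
Three model families are supported behind one interface: random forests,
support-vector machines (with calibrated probabilities) and gradient-boosted
trees.  Cross-validation is always grouped by trajectory so that frames of
one simulation can never appear on both sides of a validation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset_builder import FoldAssignment, LabeledFrameDataset
from .descriptor import ConformationDescriptor
from .errors import ModelError

__all__ = [
    "FAMILIES",
    "POSITIVE_CLASS",
    "ClassMetrics",
    "StateModel",
    "DecisionPath",
    "PathStep",
    "FeatureReport",
    "compute_metrics",
    "grouped_cv_splits",
    "train",
    "explain",
    "feature_report",
]

POSITIVE_CLASS = "active"
NEGATIVE_CLASS = "inactive"
FAMILIES = ("random-forest", "support-vector", "gradient-boosted-trees")

_BUNDLE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ClassMetrics:
    """Confusion counts plus the five derived binary-classification metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    mcc: float

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "ClassMetrics":
        """Derive precision/recall/F1/accuracy/MCC from the four counts.

        Any zero denominator yields a 0.0 sentinel with a warning, so batch
        evaluations survive degenerate confusion tables.
        """
        for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
            if v < 0:
                raise ModelError(f"count {name} is negative")
        n = tp + tn + fp + fn
        if n == 0:
            raise ModelError("empty confusion table")

        def ratio(num: float, den: float, what: str) -> float:
            if den == 0:
                warnings.warn(f"{what} undefined (zero denominator); reporting 0.0", stacklevel=3)
                return 0.0
            return num / den

        precision = ratio(tp, tp + fp, "precision")
        recall = ratio(tp, tp + fn, "recall")
        f1 = ratio(2.0 * precision * recall, precision + recall, "F1")
        accuracy = (tp + tn) / n
        mcc_den = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if mcc_den == 0:
            warnings.warn("MCC undefined (zero denominator); reporting 0.0", stacklevel=2)
            mcc = 0.0
        else:
            mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den)
        return cls(
            tp=tp, tn=tn, fp=fp, fn=fn,
            precision=precision, recall=recall, f1=f1, accuracy=accuracy, mcc=float(mcc),
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "accuracy": self.accuracy, "mcc": self.mcc,
        }

    def table(self) -> str:
        """Human-readable one-block report."""
        lines = [
            f"TP={self.tp}  FP={self.fp}  TN={self.tn}  FN={self.fn}",
            f"precision={self.precision:.4f}  recall={self.recall:.4f}  "
            f"f1={self.f1:.4f}  accuracy={self.accuracy:.4f}  mcc={self.mcc:.4f}",
        ]
        return "\n".join(lines)


def compute_metrics(predicted: Sequence[str], true: Sequence[str]) -> ClassMetrics:
    """Confusion counts and metrics with "active" as the positive class."""
    pred = np.asarray(predicted, dtype=object)
    truth = np.asarray(true, dtype=object)
    if pred.shape != truth.shape:
        raise ModelError(f"length mismatch: {pred.shape} predictions vs {truth.shape} truths")
    valid = {POSITIVE_CLASS, NEGATIVE_CLASS}
    bad = (set(pred) | set(truth)) - valid
    if bad:
        raise ModelError(f"unknown labels {sorted(bad)}; expected {sorted(valid)}")
    tp = int(np.sum((pred == POSITIVE_CLASS) & (truth == POSITIVE_CLASS)))
    tn = int(np.sum((pred == NEGATIVE_CLASS) & (truth == NEGATIVE_CLASS)))
    fp = int(np.sum((pred == POSITIVE_CLASS) & (truth == NEGATIVE_CLASS)))
    fn = int(np.sum((pred == NEGATIVE_CLASS) & (truth == POSITIVE_CLASS)))
    return ClassMetrics.from_counts(tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# model construction and training


def _make_estimator(family: str, hyperparameters: Optional[dict], seed: int):
    hp = dict(hyperparameters or {})
    if family == "random-forest":
        base = RandomForestClassifier(n_estimators=100, random_state=seed)
        unknown = set(hp) - set(base.get_params())
        if unknown:
            raise ModelError(f"unknown random-forest hyperparameters {sorted(unknown)}")
        base.set_params(**hp)
        return base
    if family == "gradient-boosted-trees":
        base = GradientBoostingClassifier(random_state=seed)
        unknown = set(hp) - set(base.get_params())
        if unknown:
            raise ModelError(f"unknown gradient-boosted-trees hyperparameters {sorted(unknown)}")
        base.set_params(**hp)
        return base
    if family == "support-vector":
        svc = SVC(probability=True, random_state=seed)
        unknown = set(hp) - set(svc.get_params())
        if unknown:
            raise ModelError(f"unknown support-vector hyperparameters {sorted(unknown)}")
        svc.set_params(**hp)
        return Pipeline([("scale", StandardScaler()), ("svc", svc)])
    raise ModelError(f"unknown model family {family!r}; choose from {FAMILIES}")


@dataclass
class StateModel:
    """A trained classifier bundle: estimator + descriptor layout + metadata."""

    family: str
    estimator: object
    pair_labels: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def _check_layout(self, pair_labels: Sequence[str]) -> None:
        if tuple(pair_labels) != tuple(self.pair_labels):
            raise ModelError(
                "descriptor pair order does not match the model's training "
                f"layout: got {list(pair_labels)[:3]}..., expected "
                f"{list(self.pair_labels)[:3]}...; no silent reordering is done"
            )

    def _active_column(self) -> int:
        classes = list(self.estimator.classes_)
        return classes.index(POSITIVE_CLASS)

    def score(self, descriptor: ConformationDescriptor) -> float:
        """Active-state probability in [0, 1] for one descriptor."""
        self._check_layout(descriptor.pair_labels)
        proba = self.estimator.predict_proba(descriptor.values.reshape(1, -1))
        return float(proba[0, self._active_column()])

    def score_matrix(self, X: np.ndarray, pair_labels: Optional[Sequence[str]] = None) -> np.ndarray:
        """Active-state probabilities for a (n, n_pairs) descriptor matrix."""
        if pair_labels is not None:
            self._check_layout(pair_labels)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.pair_labels):
            raise ModelError(f"matrix shape {X.shape} does not fit {len(self.pair_labels)} pairs")
        return self.estimator.predict_proba(X)[:, self._active_column()]

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float)).astype(object)

    def save(self, path: Union[str, Path]) -> None:
        """Persist the bundle to a single file (joblib archive)."""
        payload = {
            "format_version": _BUNDLE_FORMAT_VERSION,
            "family": self.family,
            "estimator": self.estimator,
            "pair_labels": tuple(self.pair_labels),
            "metadata": self.metadata,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "StateModel":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != _BUNDLE_FORMAT_VERSION:
            raise ModelError(f"unsupported model bundle format {version!r}")
        return cls(
            family=payload["family"],
            estimator=payload["estimator"],
            pair_labels=tuple(payload["pair_labels"]),
            metadata=payload["metadata"],
        )


def grouped_cv_splits(
    dataset: LabeledFrameDataset,
    folds: FoldAssignment,
    n_splits: int = 5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Grouped CV splits over the train partition, keyed by trajectory id.

    Returns (fit row indices, validation row indices) into the full dataset;
    every trajectory lands wholly on one side of each split.
    """
    train_rows = np.where(folds.partition_mask(dataset, "train"))[0]
    groups = dataset.traj_ids[train_rows]
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise ModelError("grouped CV needs at least two train trajectories")
    gkf = GroupKFold(n_splits=min(n_splits, n_groups))
    return [
        (train_rows[fit], train_rows[val])
        for fit, val in gkf.split(train_rows, groups=groups)
    ]


def train(
    dataset: LabeledFrameDataset,
    folds: FoldAssignment,
    family: str = "random-forest",
    hyperparameters: Optional[dict] = None,
    seed: int = 0,
    cv_splits: int = 5,
) -> StateModel:
    """Fit a state classifier on the train partition of a dataset.

    Grouped cross-validation metrics (one :class:`ClassMetrics` per split)
    are computed first and stored in the model metadata, then the final
    estimator is refit on the whole train partition.  Deterministic for a
    fixed seed.
    """
    train_mask = folds.partition_mask(dataset, "train")
    X = dataset.X[train_mask]
    y = dataset.labels[train_mask].astype(str)
    if len(X) == 0:
        raise ModelError("train partition is empty")
    present = set(y)
    if present != {POSITIVE_CLASS, NEGATIVE_CLASS}:
        raise ModelError(
            f"training data must contain both states; got only {sorted(present)}"
        )

    cv_metrics = []
    for fit_rows, val_rows in grouped_cv_splits(dataset, folds, n_splits=cv_splits):
        if len(set(dataset.labels[fit_rows])) < 2:
            continue  # a degenerate split cannot be fit; recorded by its absence
        est = _make_estimator(family, hyperparameters, seed)
        est.fit(dataset.X[fit_rows], dataset.labels[fit_rows].astype(str))
        pred = est.predict(dataset.X[val_rows]).astype(object)
        cv_metrics.append(compute_metrics(pred, dataset.labels[val_rows]).as_dict())

    estimator = _make_estimator(family, hyperparameters, seed)
    estimator.fit(X, y)
    n_active = int(np.sum(y == POSITIVE_CLASS))
    metadata = {
        "family": family,
        "seed": seed,
        "hyperparameters": dict(hyperparameters or {}),
        "fold_scheme": {
            "n_folds": folds.n_folds,
            "n_train_folds": len(folds.trajectories_in("train")),
            "n_test_folds": len(folds.trajectories_in("test")),
            "cv_splits": cv_splits,
        },
        "class_prior_active": n_active / len(y),
        "n_train_frames": int(len(y)),
        "cv_metrics": cv_metrics,
    }
    return StateModel(
        family=family,
        estimator=estimator,
        pair_labels=tuple(dataset.pair_labels),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# interpretation


@dataclass(frozen=True)
class PathStep:
    """One internal decision node crossed on the way to a leaf."""

    pair_label: str
    threshold: float
    observed: float
    branch: str  # "<=" (left) or ">" (right)


@dataclass(frozen=True)
class DecisionPath:
    """Root-to-leaf trace of one tree estimator for one descriptor."""

    steps: tuple[PathStep, ...]
    leaf_vote: str
    estimator_index: int


def _tree_estimators(model: StateModel) -> list:
    if model.family == "random-forest":
        return list(model.estimator.estimators_)
    if model.family == "gradient-boosted-trees":
        return [stage[0] for stage in model.estimator.estimators_]
    raise ModelError(f"model family {model.family!r} is not explainable (not tree-based)")


def _leaf_vote(model: StateModel, tree, node: int) -> str:
    value = tree.tree_.value[node][0]
    if model.family == "gradient-boosted-trees":
        # A single regression value: positive pushes toward classes_[1].
        classes = list(model.estimator.classes_)
        return classes[1] if float(value[0]) > 0 else classes[0]
    classes = list(model.estimator.classes_)
    return classes[int(np.argmax(value))]


def explain(
    model: StateModel,
    descriptor: ConformationDescriptor,
    estimator_index: int = 0,
) -> DecisionPath:
    """Trace the decision path of one tree estimator for one descriptor."""
    model._check_layout(descriptor.pair_labels)
    estimators = _tree_estimators(model)
    if not 0 <= estimator_index < len(estimators):
        raise ModelError(
            f"estimator index {estimator_index} out of range [0, {len(estimators)})"
        )
    est = estimators[estimator_index]
    tree = est.tree_
    x = descriptor.values
    steps: list[PathStep] = []
    node = 0
    while tree.children_left[node] != -1:
        f = int(tree.feature[node])
        threshold = float(tree.threshold[node])
        observed = float(x[f])
        if observed <= threshold:
            steps.append(PathStep(model.pair_labels[f], threshold, observed, "<="))
            node = int(tree.children_left[node])
        else:
            steps.append(PathStep(model.pair_labels[f], threshold, observed, ">"))
            node = int(tree.children_right[node])
    return DecisionPath(
        steps=tuple(steps),
        leaf_vote=_leaf_vote(model, est, node),
        estimator_index=estimator_index,
    )


@dataclass
class FeatureReport:
    """Ranked feature importances plus the feature cross-correlation screen."""

    importances: list[tuple[str, float]]
    correlation: pd.DataFrame
    high_correlation_pairs: list[tuple[str, str, float]]
    undefined_features: list[str]


def feature_report(
    model: StateModel,
    dataset: LabeledFrameDataset,
    threshold: float = 0.9,
) -> FeatureReport:
    """Importance ranking and |r| >= threshold Pearson-correlation flags.

    Constant feature columns have undefined correlations; they are reported
    in ``undefined_features`` rather than crashing the screen.
    """
    if tuple(dataset.pair_labels) != tuple(model.pair_labels):
        raise ModelError("dataset pair layout does not match the model")
    if dataset.n_frames < 2:
        raise ModelError("feature report needs at least two frames")
    if not hasattr(model.estimator, "feature_importances_"):
        raise ModelError(
            f"model family {model.family!r} does not expose feature importances"
        )
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    order = np.argsort(imp)[::-1]
    importances = [(model.pair_labels[i], float(imp[i])) for i in order]

    X = dataset.X
    stds = X.std(axis=0)
    undefined = [model.pair_labels[i] for i in np.where(stds == 0)[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    labels = list(model.pair_labels)
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)
    high = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                high.append((labels[i], labels[j], float(r)))
    return FeatureReport(
        importances=importances,
        correlation=corr_df,
        high_correlation_pairs=high,
        undefined_features=undefined,
    )
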
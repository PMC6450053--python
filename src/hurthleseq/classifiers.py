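"""Linear SVM index models with nested cross-validated cost tuning.

Both indices (Hurthle index over expression features, neoplasm index over
expression + LOH features) are linear support-vector machines whose
*continuous* decision value is the index score; binarization happens only in
the downstream cascade against learned thresholds. Features are standardized
(center/scale estimated on the training data and frozen into the model)
because the cost grid reaches 1e-4, which is only meaningful on unit-scale
features.

Cost selection uses nested cross-validation: a stratified outer loop holds
out ~10% of samples per fold for honest performance estimation, while an
inner loop on the remaining samples picks the cost with the best inner AUC.
The final cost is the most frequently selected across outer folds (ties to
the smaller, i.e. more regularized, value).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: Cost grid searched during tuning.
DEFAULT_COST_GRID: tuple[float, ...] = (1e-4, 0.001, 0.01, 0.05, 0.1, 1.0, 5.0, 10.0)

MODEL_FORMAT_VERSION = 1


def _as_array(features, feature_names: Sequence[str] | None):
    if isinstance(features, pd.DataFrame):
        if feature_names is not None:
            features = features.loc[:, list(feature_names)]
        else:
            feature_names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
    return X, list(feature_names)


@dataclass
class IndexModel:
    """A trained linear index: score(x) = w . (x - center)/scale + intercept."""

    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    cost: float
    class_cost_ratio: float = 1.0
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    training_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValueError("weights and feature_names length mismatch")

    def decision_scores(self, features) -> np.ndarray:
        """Continuous decision values; feature names must match when a DataFrame."""
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in features.columns]
            if missing:
                raise ValueError(f"feature vector is missing model features: {missing[:5]}")
            X = features.loc[:, self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, got {X.shape[1]}"
                )
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite (impute LOH markers first)")
        if self.center is not None:
            X = (X - self.center) / self.scale
        return X @ self.weights + self.intercept

    def to_json(self, path=None) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "cost": self.cost,
            "class_cost_ratio": self.class_cost_ratio,
            "center": None if self.center is None else self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "training_metadata": self.training_metadata,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "IndexModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {payload.get('format_version')}")
        return cls(
            feature_names=payload["feature_names"],
            weights=np.asarray(payload["weights"], dtype=float),
            intercept=payload["intercept"],
            cost=payload["cost"],
            class_cost_ratio=payload.get("class_cost_ratio", 1.0),
            center=None if payload["center"] is None else np.asarray(payload["center"]),
            scale=None if payload["scale"] is None else np.asarray(payload["scale"]),
            training_metadata=payload.get("training_metadata", {}),
        )


def train_linear_svm(
    features,
    labels,
    cost: float,
    class_cost_ratio: float = 1.0,
    feature_names: Sequence[str] | None = None,
) -> IndexModel:
    """Fit a linear SVM (hinge loss, L2 regularization) with per-class cost weighting.

    ``class_cost_ratio`` multiplies the misclassification cost of the
    positive class, trading specificity for sensitivity under imbalance.
    """
    X, names = _as_array(features, feature_names)
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite (impute LOH markers first)")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("training labels must contain exactly two classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - center) / scale
    svc = SVC(
        kernel="linear",
        C=cost,
        class_weight={0: 1.0, 1: float(class_cost_ratio)},
    )
    svc.fit(Xs, y)
    return IndexModel(
        feature_names=names,
        weights=svc.coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        cost=float(cost),
        class_cost_ratio=float(class_cost_ratio),
        center=center,
        scale=scale,
        training_metadata={"n_samples": int(len(y)),
                           "n_support": int(svc.n_support_.sum())},
    )


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties averaged; errors on one class."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def sens_spec_at(scores, labels, cutoff: float) -> tuple[float, float]:
    """(sensitivity, specificity) at a cutoff; score > cutoff is a positive call."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not y.any() or y.all():
        raise ValueError("need both classes to compute sensitivity and specificity")
    sensitivity = float((s[y] > cutoff).mean())
    specificity = float((s[~y] <= cutoff).mean())
    return sensitivity, specificity


@dataclass
class CVReport:
    """Outer-fold results of a nested cross-validation run.

    ``auc`` is the mean of per-fold held-out AUCs (the resampling estimate):
    decision-score *scales* differ between folds when the inner loops select
    different costs, so ranking raw scores pooled across folds would mix
    incomparable scales. The pooled scores are retained for plotting and for
    sensitivity/specificity at a cutoff (0 is every fold model's decision
    boundary, so the cutoff metrics are comparable), and ``pooled_auc``
    records the naive pooled statistic.
    """

    scores: np.ndarray
    labels: np.ndarray
    fold_ids: np.ndarray
    outer_test_indices: list[np.ndarray]
    outer_train_indices: list[np.ndarray]
    selected_costs: list[float]
    auc: float
    pooled_auc: float
    fold_aucs: list[float]
    sensitivity: float
    specificity: float
    cutoff: float
    seed: int


def nested_cv_tune(
    features,
    labels,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    outer_folds: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    class_cost_ratio: float = 1.0,
    cutoff: float = 0.0,
    feature_names: Sequence[str] | None = None,
) -> tuple[float, CVReport]:
    """Nested stratified cross-validation over the cost grid.

    Outer folds hold out ~1/outer_folds of samples for evaluation; for each
    outer fold, the inner loop (on the outer-training samples only) selects
    the cost maximizing mean inner-validation AUC. Outer held-out scores are
    pooled into the report. Returns (best_cost, report) where best_cost is
    the most frequently selected cost across outer folds, ties broken toward
    the smaller value. Deterministic given (data, seed).
    """
    if not len(cost_grid):
        raise ValueError("cost_grid must be non-empty")
    X, names = _as_array(features, feature_names)
    y = np.asarray(labels).astype(int)
    _, counts = np.unique(y, return_counts=True)
    if len(counts) != 2:
        raise ValueError("need two classes")
    if counts.min() < outer_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify "
            f"{outer_folds} outer folds -- reduce outer_folds"
        )

    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    pooled_scores = np.empty(len(y))
    fold_ids = np.empty(len(y), dtype=int)
    selected: list[float] = []
    test_idx_list: list[np.ndarray] = []
    train_idx_list: list[np.ndarray] = []

    for k, (tr, te) in enumerate(outer.split(X, y)):
        inner = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=seed + 1000 + k
        )
        inner_auc = []
        for cost in cost_grid:
            aucs = []
            for itr, ite in inner.split(X[tr], y[tr]):
                model = train_linear_svm(
                    X[tr][itr], y[tr][itr], cost, class_cost_ratio, names
                )
                aucs.append(roc_auc(model.decision_scores(X[tr][ite]), y[tr][ite]))
            inner_auc.append(np.mean(aucs))
        # ties toward the smaller (more regularized) cost
        best = min(
            range(len(cost_grid)),
            key=lambda i: (-np.round(inner_auc[i], 12), cost_grid[i]),
        )
        cost_k = float(cost_grid[best])
        selected.append(cost_k)
        model = train_linear_svm(X[tr], y[tr], cost_k, class_cost_ratio, names)
        pooled_scores[te] = model.decision_scores(X[te])
        fold_ids[te] = k
        test_idx_list.append(np.asarray(te))
        train_idx_list.append(np.asarray(tr))

    votes = Counter(selected)
    top = max(votes.values())
    best_cost = min(c for c, v in votes.items() if v == top)
    sens, spec = sens_spec_at(pooled_scores, y, cutoff)
    fold_aucs = [roc_auc(pooled_scores[te], y[te]) for te in test_idx_list]
    report = CVReport(
        scores=pooled_scores,
        labels=y,
        fold_ids=fold_ids,
        outer_test_indices=test_idx_list,
        outer_train_indices=train_idx_list,
        selected_costs=selected,
        auc=float(np.mean(fold_aucs)),
        pooled_auc=roc_auc(pooled_scores, y),
        fold_aucs=fold_aucs,
        sensitivity=sens,
        specificity=spec,
        cutoff=cutoff,
        seed=seed,
    )
    logger.info("nested CV: pooled AUC %.3f, best cost %g (votes %s)",
                report.auc, best_cost, dict(votes))
    return best_cost, report


def fit_index_model(
    features,
    labels,
    seed: int = 0,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    outer_folds: int = 10,
    inner_folds: int = 5,
    class_cost_ratio: float = 1.0,
    feature_names: Sequence[str] | None = None,
) -> tuple[IndexModel, CVReport]:
    """Nested-CV cost tuning followed by a final fit on all samples."""
    best_cost, report = nested_cv_tune(
        features, labels, cost_grid, outer_folds, inner_folds, seed,
        class_cost_ratio, feature_names=feature_names,
    )
    model = train_linear_svm(features, labels, best_cost, class_cost_ratio,
                             feature_names)
    model.training_metadata.update(
        {"cv_auc": report.auc, "cv_sensitivity": report.sensitivity,
         "cv_specificity": report.specificity, "seed": seed,
         "selected_costs": report.selected_costs}
    )
    return model, report
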
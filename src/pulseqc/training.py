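"""Re-deriving quality classifiers from labeled corpora.

The published classifier was identified by comparing KNN, L2-regularized
logistic regression, and three SVM kernels under 10-fold cross-validation,
sweeping the standard length over 3..100, and simplifying the logistic
model with recursive feature elimination (RFE).  This module reproduces
that harness on any labeled corpus; the "normal" class is positive
throughout, so sensitivity is the true-normal rate and specificity the
true-abnormal rate.

Standard model fits go through scikit-learn; the RFE loop (fit, drop the
feature with the smallest absolute weight, repeat) is implemented directly
because the elimination order is the quantity of interest.  All stochastic
steps are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import TrainingError, UndefinedMetricError, ValidationError
from .quality_model import ABNORMAL, NORMAL, QualityModelSpec
from .standardize import StandardizedSegment

ALGORITHMS = ("logistic_l2", "knn", "svm_rbf", "svm_linear", "svm_poly3")


@dataclass
class LabeledCorpus:
    """Standardized segments with parallel normal/abnormal labels."""

    segments: List[StandardizedSegment]
    labels: List[str]
    anomaly_kinds: Optional[List[Optional[str]]] = None

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.labels):
            raise ValidationError("segments and labels must be parallel")
        if not self.segments:
            raise ValidationError("corpus must be non-empty")
        lengths = {s.standard_length for s in self.segments}
        if len(lengths) != 1:
            raise ValidationError("all segments must share one standard length")
        for label in self.labels:
            if label not in (NORMAL, ABNORMAL):
                raise ValidationError(f"label must be normal/abnormal, got {label!r}")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def standard_length(self) -> int:
        return self.segments[0].standard_length

    def feature_matrix(self, feature_indices: Optional[Sequence[int]] = None) -> np.ndarray:
        """n x k matrix of feature points (1-based ``feature_indices``)."""
        X = np.vstack([s.values for s in self.segments])
        if feature_indices is None:
            return X
        idx = _validate_indices(feature_indices, self.standard_length)
        return X[:, [k - 1 for k in idx]]

    def binary_labels(self) -> np.ndarray:
        """1 for normal (positive class), 0 for abnormal."""
        return np.asarray([1 if l == NORMAL else 0 for l in self.labels], dtype=int)


@dataclass
class TrainingConfig:
    """Algorithm choice, hyperparameter grids, and CV settings.

    Grid defaults follow the published search: KNN neighbors 1..50, SVM
    cost {0.01, 0.1, 1, 10, 100} x gamma {0.001, 0.01, 0.1, 1, 10}, 10-fold
    cross-validation.  ``l2_strength`` is the penalty weight in the standard
    regularized-loss parameterization (scikit-learn's C = 1/l2_strength).
    """

    algorithm: str = "logistic_l2"
    knn_neighbor_grid: Sequence[int] = tuple(range(1, 51))
    svm_cost_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: Sequence[float] = (0.001, 0.01, 0.1, 1.0, 10.0)
    folds: int = 10
    rng_seed: int = 0
    l2_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.folds < 2:
            raise ValidationError("folds must be at least 2")
        if not self.knn_neighbor_grid or not self.svm_cost_grid or not self.svm_gamma_grid:
            raise ValidationError("hyperparameter grids must be non-empty")
        if not self.l2_strength > 0:
            raise ValidationError("l2_strength must be positive")


@dataclass
class CVMetrics:
    """Mean +- sd of the metric triple over cross-validation folds."""

    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float


@dataclass
class FeatureRanking:
    """Feature points ordered most-important-first (RFE reverse elimination)."""

    order: Tuple[int, ...]

    def __post_init__(self) -> None:
        L = len(self.order)
        if sorted(self.order) != list(range(1, L + 1)):
            raise ValidationError("order must be a permutation of 1..L")


def _validate_indices(feature_indices: Sequence[int], L: int) -> List[int]:
    idx = list(feature_indices)
    if not idx:
        raise ValidationError("feature_indices must be non-empty")
    for k in idx:
        if not (1 <= k <= L):
            raise ValidationError(f"feature index {k} outside [1, {L}]")
    return idx


def compute_metrics(
    predicted: Sequence[str], truth: Sequence[str]
) -> Tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with normal as positive class."""
    if len(predicted) != len(truth) or len(truth) == 0:
        raise ValidationError("predicted and truth must be equal-length, non-empty")
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    n_normal = int(np.sum(true == NORMAL))
    n_abnormal = int(np.sum(true == ABNORMAL))
    if n_normal == 0:
        raise UndefinedMetricError("sensitivity undefined: no true normal segments")
    if n_abnormal == 0:
        raise UndefinedMetricError("specificity undefined: no true abnormal segments")
    accuracy = float(np.mean(pred == true))
    sensitivity = float(np.sum((pred == NORMAL) & (true == NORMAL)) / n_normal)
    specificity = float(np.sum((pred == ABNORMAL) & (true == ABNORMAL)) / n_abnormal)
    return accuracy, sensitivity, specificity


def _logistic_estimator(l2_strength: float) -> LogisticRegression:
    # default penalty is L2 with strength 1/C
    return LogisticRegression(
        C=1.0 / l2_strength,
        solver="lbfgs",
        tol=1e-8,
        max_iter=10_000,
    )


def fit_logistic_l2(
    corpus: LabeledCorpus,
    feature_indices: Sequence[int],
    l2_strength: float = 1.0,
) -> QualityModelSpec:
    """Fit the L2-penalized logistic model on the given feature points."""
    idx = _validate_indices(feature_indices, corpus.standard_length)
    y = corpus.binary_labels()
    if len(np.unique(y)) < 2:
        raise TrainingError("training corpus must contain both classes")
    X = corpus.feature_matrix(idx)
    clf = _logistic_estimator(l2_strength).fit(X, y)
    weights = {k: float(w) for k, w in zip(idx, clf.coef_[0])}
    return QualityModelSpec(
        standard_length=corpus.standard_length,
        intercept=float(clf.intercept_[0]),
        weights=weights,
        decision_threshold=0.5,
    )


def _grid(config: TrainingConfig) -> List[Tuple[Dict[str, float], object]]:
    """(hyperparameters, estimator) pairs for the configured algorithm."""
    if config.algorithm == "logistic_l2":
        return [
            ({"l2_strength": config.l2_strength}, _logistic_estimator(config.l2_strength))
        ]
    if config.algorithm == "knn":
        return [
            ({"n_neighbors": int(n)}, KNeighborsClassifier(n_neighbors=int(n)))
            for n in config.knn_neighbor_grid
        ]
    if config.algorithm == "svm_linear":
        return [
            ({"cost": c}, SVC(kernel="linear", C=c)) for c in config.svm_cost_grid
        ]
    kernel = {"svm_rbf": "rbf", "svm_poly3": "poly"}[config.algorithm]
    grid = []
    for c in config.svm_cost_grid:
        for g in config.svm_gamma_grid:
            est = SVC(kernel=kernel, C=c, gamma=g, degree=3)
            grid.append(({"cost": c, "gamma": g}, est))
    return grid


def cross_validate(
    corpus: LabeledCorpus,
    config: TrainingConfig,
    feature_indices: Optional[Sequence[int]] = None,
) -> Tuple[CVMetrics, Dict[str, float]]:
    """Stratified seeded k-fold CV with grid search by mean accuracy.

    Returns the best setting's metric triple (mean +- sd over folds) and the
    selected hyperparameters.
    """
    y = corpus.binary_labels()
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.folds:
        raise ValidationError(
            f"each class needs at least {config.folds} members for "
            f"{config.folds}-fold stratified CV"
        )
    X = corpus.feature_matrix(feature_indices)
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.rng_seed % (2**31)
    )
    splits = list(skf.split(X, y))
    best: Optional[Tuple[float, CVMetrics, Dict[str, float]]] = None
    for params, estimator in _grid(config):
        acc, sens, spec = [], [], []
        for train_idx, test_idx in splits:
            est = estimator.fit(X[train_idx], y[train_idx])
            pred = est.predict(X[test_idx])
            yt = y[test_idx]
            acc.append(float(np.mean(pred == yt)))
            sens.append(float(np.sum((pred == 1) & (yt == 1)) / np.sum(yt == 1)))
            spec.append(float(np.sum((pred == 0) & (yt == 0)) / np.sum(yt == 0)))
        metrics = CVMetrics(
            accuracy_mean=float(np.mean(acc)),
            accuracy_sd=float(np.std(acc, ddof=1)),
            sensitivity_mean=float(np.mean(sens)),
            sensitivity_sd=float(np.std(sens, ddof=1)),
            specificity_mean=float(np.mean(spec)),
            specificity_sd=float(np.std(spec, ddof=1)),
        )
        if best is None or metrics.accuracy_mean > best[0]:
            best = (metrics.accuracy_mean, metrics, params)
    assert best is not None
    return best[1], best[2]


def rfe_rank(corpus: LabeledCorpus, l2_strength: float = 1.0) -> FeatureRanking:
    """Recursive feature elimination ranking of the L feature points.

    Repeatedly fits the L2 logistic model on the surviving features and
    removes the one with the smallest absolute weight (features share the
    [0,1] scale after standardization, so absolute weight is comparable);
    the ranking is the reverse elimination order.
    """
    y = corpus.binary_labels()
    if len(np.unique(y)) < 2:
        raise TrainingError("training corpus must contain both classes")
    X = corpus.feature_matrix()
    remaining = list(range(1, corpus.standard_length + 1))
    eliminated: List[int] = []
    while len(remaining) > 1:
        cols = [k - 1 for k in remaining]
        clf = _logistic_estimator(l2_strength).fit(X[:, cols], y)
        weakest = int(np.argmin(np.abs(clf.coef_[0])))
        eliminated.append(remaining.pop(weakest))
    order = tuple(remaining + eliminated[::-1])
    return FeatureRanking(order=order)


def sweep_standard_length(
    raw_segments: Sequence,
    labels: Sequence[str],
    lengths: Sequence[int],
    config: TrainingConfig,
) -> pd.DataFrame:
    """Restandardize at each trial length and cross-validate the classifier.

    Trial lengths must lie in [3, 100]; 100 points retain all clinically
    useful bandwidth (<= 25 Hz over a <= 2 s cycle).
    """
    from .standardize import standardize

    lengths = list(lengths)
    if not lengths:
        raise ValidationError("lengths must be non-empty")
    for L in lengths:
        if not (3 <= L <= 100):
            raise ValidationError(f"standard length {L} outside [3, 100]")
    rows = []
    for L in lengths:
        corpus = LabeledCorpus(
            segments=[standardize(s, L) for s in raw_segments],
            labels=list(labels),
        )
        metrics, _ = cross_validate(corpus, config)
        rows.append({"standard_length": L, **vars(metrics)})
    return pd.DataFrame(rows)


def sweep_feature_count(
    corpus: LabeledCorpus,
    ranking: FeatureRanking,
    config: TrainingConfig,
    ks: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Cross-validate with the top-k ranked features, k = L down to 1."""
    L = corpus.standard_length
    if len(ranking.order) != L:
        raise ValidationError("ranking does not match the corpus standard length")
    if ks is None:
        ks = list(range(L, 0, -1))
    ks = list(ks)
    for k in ks:
        if not (1 <= k <= L):
            raise ValidationError(f"feature count {k} outside [1, {L}]")
    rows = []
    for k in ks:
        metrics, _ = cross_validate(corpus, config, feature_indices=ranking.order[:k])
        rows.append({"n_features": k, **vars(metrics)})
    return pd.DataFrame(rows)


def evaluate_model(corpus: LabeledCorpus, model: QualityModelSpec) -> Dict[str, float]:
    """Accuracy/sensitivity/specificity at the model threshold, plus ROC AUC.

    The AUC integrates the ROC curve (swept over all probability
    thresholds) with the trapezoid rule.
    """
    from .quality_model import classify

    probs = np.asarray([classify(model, s).probability for s in corpus.segments])
    predicted = [NORMAL if p >= model.decision_threshold else ABNORMAL for p in probs]
    accuracy, sensitivity, specificity = compute_metrics(predicted, corpus.labels)
    fpr, tpr, _ = roc_curve(corpus.binary_labels(), probs)
    auc = float(np.trapezoid(tpr, fpr))
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "auc": auc,
    }


def split_corpus_by_record(
    corpus: LabeledCorpus, test_fraction: float = 0.2, rng_seed: int = 0
) -> Tuple[LabeledCorpus, LabeledCorpus]:
    """Record-level train/test split (segments of one record never straddle)."""
    if not (0.0 < test_fraction < 1.0):
        raise ValidationError("test_fraction must lie strictly in (0,1)")
    rng = np.random.default_rng(rng_seed)
    record_ids = sorted({s.source.record_id for s in corpus.segments})
    n_test = max(1, int(round(test_fraction * len(record_ids))))
    if n_test >= len(record_ids):
        raise ValidationError("too few records to split")
    test_ids = set(rng.choice(record_ids, size=n_test, replace=False))

    def subset(keep_test: bool) -> LabeledCorpus:
        idx = [
            i
            for i, s in enumerate(corpus.segments)
            if (s.source.record_id in test_ids) == keep_test
        ]
        return LabeledCorpus(
            segments=[corpus.segments[i] for i in idx],
            labels=[corpus.labels[i] for i in idx],
            anomaly_kinds=None
            if corpus.anomaly_kinds is None
            else [corpus.anomaly_kinds[i] for i in idx],
        )

    return subset(False), subset(True)
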
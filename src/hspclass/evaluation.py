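"""Confusion-matrix metrics, ROC/AUC, cross-validation and grid search.

Metric definitions (all on a binary confusion matrix):

* sensitivity = 100 * TP / (TP + FN)
* specificity = 100 * TN / (TN + FP)
* accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)
* MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC of 1 is perfect prediction, 0 random assignment, -1 perfect inversion.
When a sensitivity/specificity denominator is empty the metric is reported
as NaN with a warning; MCC with a zero marginal is defined as 0.

Cross-validation supports stratified five-fold and leave-one-out schemes.
Fold results are pooled (micro-averaged): confusion counts are summed over
folds and one metrics report is computed from the pooled counts, with
held-out decision values concatenated for the AUC.  Pooling is the only
aggregation that is also well-defined for leave-one-out folds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .errors import HspClassError
from .features import encode_dataset
from .sequence_io import ProteinRecord
from .svm import BinaryModel, KernelConfig, train_binary


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise HspClassError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity/specificity/accuracy in percent, MCC in [-1, 1], optional AUC."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def tally_confusion(
    actual: Sequence, predicted: Sequence, positive_class=1
) -> ConfusionCounts:
    """Count TP/TN/FP/FN with ``positive_class`` as the positive label."""
    a = np.asarray(actual)
    p = np.asarray(predicted)
    if a.size == 0:
        raise HspClassError("cannot tally empty label vectors")
    if a.shape != p.shape:
        raise HspClassError(f"label vectors differ in length: {a.shape} vs {p.shape}")
    pos_a = a == positive_class
    pos_p = p == positive_class
    return ConfusionCounts(
        tp=int((pos_a & pos_p).sum()),
        tn=int((~pos_a & ~pos_p).sum()),
        fp=int((~pos_a & pos_p).sum()),
        fn=int((pos_a & ~pos_p).sum()),
    )


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Sensitivity, specificity, accuracy and MCC from confusion counts."""
    if counts.total < 1:
        raise HspClassError("metrics need at least one prediction")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    if tp + fn == 0:
        warnings.warn("no positive examples: sensitivity undefined (NaN)")
        sens = math.nan
    else:
        sens = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative examples: specificity undefined (NaN)")
        spec = math.nan
    else:
        spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / counts.total

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc, mcc=mcc, auc=auc)


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """Threshold sweep over distinct scores.

    Returns an (n_points, 2) array of (false positive rate, sensitivity)
    pairs, monotone from (0, 0) to (1, 1).  A point is emitted per distinct
    score value, predicting positive at score >= threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.size == 0:
        raise HspClassError("scores and labels must be non-empty and aligned")
    if not np.isfinite(s).all():
        raise HspClassError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise HspClassError("ROC analysis requires both classes")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = (y[order] == 1).astype(int)
    tp_cum = np.cumsum(pos_sorted)
    fp_cum = np.cumsum(1 - pos_sorted)
    # keep only the last index of each tied score block
    last_of_block = np.nonzero(np.diff(s_sorted, append=-np.inf) != 0)[0]
    tpr = tp_cum[last_of_block] / n_pos
    fpr = fp_cum[last_of_block] / n_neg
    pts = np.column_stack([np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])])
    return pts


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Equals the Mann-Whitney pair-counting statistic: the fraction of
    (positive, negative) pairs where the positive outscores the negative,
    ties counting one half.
    """
    pts = roc_curve(scores, labels)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


@dataclass(frozen=True)
class CVPlan:
    """A fold assignment: ``fold_of[i]`` is the fold holding record *i* out."""

    scheme: str  # "five_fold" or "loocv"
    fold_of: np.ndarray
    stratified: bool
    seed: int

    @property
    def n_folds(self) -> int:
        return int(self.fold_of.max()) + 1

    @property
    def n(self) -> int:
        return int(self.fold_of.size)


SCHEMES = ("five_fold", "loocv")


def make_cv_plan(labels: Sequence, scheme: str, seed: int = 0) -> CVPlan:
    """Build a stratified five-fold or leave-one-out fold assignment.

    Five-fold stratification keeps per-class counts within one of perfect
    balance across folds; leave-one-out emits one singleton fold per record.
    Deterministic given the seed.
    """
    y = np.asarray(labels)
    n = y.size
    if scheme not in SCHEMES:
        raise HspClassError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    fold_of = np.empty(n, dtype=int)
    if scheme == "five_fold":
        if n < 5:
            raise HspClassError(f"five-fold CV needs at least 5 records, got {n}")
        counts = pd.Series(y).value_counts()
        if counts.min() < 5:
            raise HspClassError(
                "five-fold stratification needs at least 5 records per class "
                f"(smallest class has {int(counts.min())})"
            )
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), y)):
            fold_of[test_idx] = fold
        return CVPlan("five_fold", fold_of, stratified=True, seed=seed)
    if n < 2:
        raise HspClassError(f"leave-one-out CV needs at least 2 records, got {n}")
    for fold, (_, test_idx) in enumerate(LeaveOneOut().split(np.zeros(n))):
        fold_of[test_idx] = fold
    return CVPlan("loocv", fold_of, stratified=False, seed=seed)


@dataclass
class CVResult:
    pooled: MetricsReport
    pooled_counts: ConfusionCounts
    per_fold: list[ConfusionCounts]
    scores: np.ndarray  # held-out decision values, original record order
    predictions: np.ndarray  # held-out +/-1 predictions, original record order


def cross_validate(
    records: Sequence[ProteinRecord],
    labels: Sequence[int],
    encoding: str,
    config: KernelConfig,
    plan: CVPlan,
    seed: int = 0,
) -> CVResult:
    """Train on each fold's complement, score the fold, pool the confusion.

    Returns pooled metrics (AUC over the concatenated held-out scores) plus
    the per-fold confusion counts.
    """
    y = np.asarray(labels)
    if plan.n != len(records) or plan.n != y.size:
        raise HspClassError(
            f"CV plan covers {plan.n} records but {len(records)} were given"
        )
    X, _ = encode_dataset(records, encoding=encoding)
    scores = np.empty(plan.n, dtype=float)
    predictions = np.empty(plan.n, dtype=int)
    per_fold: list[ConfusionCounts] = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for fold in range(plan.n_folds):
        test_mask = plan.fold_of == fold
        train_mask = ~test_mask
        y_train = y[train_mask]
        if len(set(y_train.tolist())) < 2:
            raise HspClassError(
                f"fold {fold}: training complement contains a single class"
            )
        model = train_binary(
            X[train_mask], y_train, config, seed=seed, encoding=encoding
        )
        d = model.decision_values(X[test_mask])
        scores[test_mask] = d
        predictions[test_mask] = np.where(d >= 0, 1, -1)
        fold_counts = tally_confusion(y[test_mask], predictions[test_mask])
        per_fold.append(fold_counts)
        pooled_counts = pooled_counts + fold_counts
    pooled_auc = auc(scores, y)
    pooled = compute_metrics(pooled_counts, auc=pooled_auc)
    return CVResult(
        pooled=pooled,
        pooled_counts=pooled_counts,
        per_fold=per_fold,
        scores=scores,
        predictions=predictions,
    )


def default_grid() -> list[KernelConfig]:
    """The default hyper-parameter search grid.

    Polynomial degrees 1-5 and rbf gammas spanning 5e-4 to 1e-1, crossed
    with cost ratios 1-40; the ranges bracket the winning configurations
    reported for composition-encoded HSP models.
    """
    grid: list[KernelConfig] = []
    for j in (1.0, 2.0, 4.0, 5.0, 7.0, 10.0, 20.0, 40.0):
        for d in (1, 2, 3, 4, 5):
            grid.append(KernelConfig.polynomial(degree=d, cost_ratio=j))
        for g in (5e-4, 5e-3, 1e-2, 5e-2, 1e-1):
            grid.append(KernelConfig.rbf(gamma=g, cost_ratio=j))
    return grid


def grid_search(
    records: Sequence[ProteinRecord],
    labels: Sequence[int],
    encoding: str,
    grid: Sequence[KernelConfig],
    plan: CVPlan,
    seed: int = 0,
) -> tuple[KernelConfig, pd.DataFrame]:
    """Cross-validate every config; select by accuracy, then MCC, then grid order."""
    if len(grid) == 0:
        raise HspClassError("hyper-parameter grid is empty")
    rows = []
    best_idx = 0
    best_key: tuple[float, float] | None = None
    for i, config in enumerate(grid):
        result = cross_validate(records, labels, encoding, config, plan, seed=seed)
        m = result.pooled
        rows.append(
            {
                "config": config.describe(),
                "kernel": config.kernel,
                "degree": config.degree,
                "gamma": config.gamma,
                "cost_ratio": config.cost_ratio,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "mcc": m.mcc,
                "auc": m.auc,
            }
        )
        key = (m.accuracy, m.mcc)
        if best_key is None or key > best_key:
            best_key = key
            best_idx = i
    return grid[best_idx], pd.DataFrame(rows)
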
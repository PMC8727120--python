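"""Soft-margin SVM classification and the evaluation metrics of the pipeline.

The classifier is the standard soft-margin SVM (hinge loss with penalty C),
one-vs-one for more than two classes, with decision scores taken as the
signed distance to the hyperplane for ROC/AUC. Metrics follow the usual
confusion-count formulas: accuracy, sensitivity (recall of the positive
class), specificity, precision, F1, and a rank-statistic AUC that counts
tied scores as half. Metrics whose denominator is zero are reported as
``None`` (undefined), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Any, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "ConfusionCounts",
    "MetricsReport",
    "train_svm",
    "confusion",
    "auc_score",
    "metrics",
    "grid_search",
]


@dataclass(frozen=True)
class SVMConfig:
    """Penalty C, kernel ('linear' or 'rbf'), one-vs-one multiclass."""

    c_penalty: float = 1.0
    kernel: str = "linear"

    def __post_init__(self) -> None:
        if self.c_penalty <= 0:
            raise ValueError(f"c_penalty must be positive, got {self.c_penalty}")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-derived metrics; undefined ratios surface as ``None``."""

    counts: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None

    def as_dict(self) -> dict[str, Any]:
        return {
            "tp": self.counts.tp,
            "fn": self.counts.fn,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
        }


def train_svm(x: np.ndarray, y: Sequence, cfg: SVMConfig = SVMConfig()) -> SVC:
    """Fit a soft-margin SVM; one-vs-one decisions for more than two classes."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(
        C=cfg.c_penalty,
        kernel=cfg.kernel,
        decision_function_shape="ovo",
        random_state=0,
    )
    clf.fit(x, y)
    return clf


def confusion(y_true: Sequence, y_pred: Sequence, positive_label=1) -> ConfusionCounts:
    """Binary confusion counts with respect to ``positive_label``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def auc_score(y_true: Sequence, scores: Sequence, positive_label=1) -> float:
    """Area under the ROC curve as the rank statistic
    P(score_pos > score_neg) + 0.5 * P(tie), via midranks."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y_true == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores, method="average")
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(
    c: ConfusionCounts,
    y_true: Sequence | None = None,
    scores: Sequence | None = None,
    positive_label=1,
) -> MetricsReport:
    """Accuracy/sensitivity/specificity/precision/F1 from counts; AUC from
    the optional decision scores."""
    accuracy = _ratio(c.tp + c.tn, c.total)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.fp + c.tn)
    precision = _ratio(c.tp, c.tp + c.fp)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    auc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("AUC needs y_true alongside scores")
        auc = auc_score(y_true, scores, positive_label)
    return MetricsReport(
        counts=c,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        auc=auc,
    )


def stratified_folds(labels: Sequence, n_folds: int, seed: int) -> list[np.ndarray]:
    """Test-index arrays of a stratified k-fold partition (each subject in
    exactly one test fold)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if n_folds < 2:
        raise ValueError(f"need at least 2 folds, got {n_folds}")
    if counts.min() < n_folds:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {small!r} has only {counts.min()} members for {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def grid_search(
    evaluate,
    param_grid: dict[str, Sequence],
) -> tuple[dict[str, Any], list[tuple[dict[str, Any], float]]]:
    """Exhaustive search over the cartesian grid, maximizing ``evaluate(params)``.

    Ties break to the first point in lexicographic grid order (the order the
    values are listed). Returns (best_params, [(params, score), ...]).
    """
    names = list(param_grid)
    table: list[tuple[dict[str, Any], float]] = []
    best: tuple[dict[str, Any], float] | None = None
    for values in _iterproduct(*(param_grid[n] for n in names)):
        params = dict(zip(names, values))
        score = float(evaluate(params))
        table.append((params, score))
        if best is None or score > best[1]:
            best = (params, score)
    if best is None:
        raise ValueError("empty parameter grid")
    return best[0], table


#: Default hyperparameter grid for the PCANet feature extractor; k is
#: restricted to odd values because same-size zero padding needs odd kernels.
DEFAULT_PCANET_GRID: dict[str, Sequence] = {
    "k": (3, 5, 7),
    "c1": (2, 3, 4, 5, 6),
    "c2": (2, 3, 4, 5, 6),
    "overlap_r": (0.0, 0.2, 0.4, 0.6),
    "beta": (5, 10, 15, 20, 25),
}
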
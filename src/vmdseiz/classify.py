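"""SVM classification with stratified k-fold cross-validation and the
seizure-detection metrics (accuracy, sensitivity, specificity, AUC).

The positive class is ictal (label 1). Sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP); AUC is the Mann-Whitney rank statistic of the SVM
decision scores (probability that a random ictal epoch outscores a random
interictal one, ties half-credited).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix
from .signal_io import ParameterError


@dataclass
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ParameterError("C must be positive")
        if self.kernel not in ("rbf", "linear"):
            raise ParameterError(f"kernel must be 'rbf' or 'linear', got {self.kernel!r}")


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.TN + other.TN,
            self.FP + other.FP,
            self.FN + other.FN,
        )


@dataclass
class ClassifierReport:
    """Per-fold and pooled evaluation of one cross-validated run."""

    per_fold: list[ConfusionCounts]
    fold_auc: list[float]
    pooled: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    seed: int
    fold_assignment: np.ndarray

    def to_dict(self) -> dict:
        return {
            "per_fold": [
                {"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN, "auc": a}
                for c, a in zip(self.per_fold, self.fold_auc)
            ],
            "pooled": {
                "TP": self.pooled.TP,
                "TN": self.pooled.TN,
                "FP": self.pooled.FP,
                "FN": self.pooled.FN,
            },
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "seed": self.seed,
            "fold_assignment": [int(f) for f in self.fold_assignment],
        }


class TrainedSVM:
    """Standardizer + SVC fitted together; exposes scores and hard labels."""

    def __init__(self, scaler: StandardScaler, svc: SVC):
        self._scaler = scaler
        self._svc = svc

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(self._scaler.transform(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._svc.predict(self._scaler.transform(x))


def train_svm(
    x: np.ndarray, y: np.ndarray, cfg: SVMConfig | None = None
) -> TrainedSVM:
    """Fit a standardized SVM; raises on single-class or non-finite input."""
    if cfg is None:
        cfg = SVMConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ParameterError("training data contains a single class")
    if not np.all(np.isfinite(x)):
        raise ParameterError("features contain non-finite values")
    scaler = StandardScaler().fit(x)
    svc = SVC(
        kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma, random_state=cfg.seed
    ).fit(scaler.transform(x), y)
    return TrainedSVM(scaler, svc)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with half-credit for ties; NaN if a class is empty."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)  # average ranks handle ties -> half credit
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(
    c: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity from counts; AUC from scores.

    A ratio with an empty denominator (no positives, or no negatives) is
    reported as NaN rather than zero.
    """
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else math.nan
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else math.nan
    acc = (c.TP + c.TN) / c.total if c.total > 0 else math.nan
    auc = (
        rank_auc(scores, labels)
        if scores is not None and labels is not None
        else math.nan
    )
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "auc": auc,
    }


def cross_validate(
    features: FeatureMatrix,
    mask: np.ndarray | None = None,
    cfg: SVMConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified k-fold CV of the SVM on the masked channels.

    Standardization is fitted on each training split only. Per-fold confusion
    counts and AUCs are reported alongside pooled counts; the headline
    accuracy/sensitivity/specificity come from the pooled counts and the
    headline AUC is the mean of the per-fold AUCs.
    """
    if cfg is None:
        cfg = SVMConfig()
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    x = (
        features.select_channels(np.asarray(mask))
        if mask is not None
        else features.values
    )
    y = features.labels
    for cls in np.unique(y):
        if (y == cls).sum() < n_folds:
            raise ParameterError(
                f"class {cls} has {(y == cls).sum()} samples < n_folds {n_folds}"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold: list[ConfusionCounts] = []
    fold_auc: list[float] = []
    assignment = np.empty(y.size, dtype=int)
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        assignment[te] = fold
        model = train_svm(x[tr], y[tr], cfg)
        pred = model.predict(x[te])
        score = model.decision_scores(x[te])
        c = ConfusionCounts(
            TP=int(((pred == 1) & (y[te] == 1)).sum()),
            TN=int(((pred == 0) & (y[te] == 0)).sum()),
            FP=int(((pred == 1) & (y[te] == 0)).sum()),
            FN=int(((pred == 0) & (y[te] == 1)).sum()),
        )
        per_fold.append(c)
        fold_auc.append(rank_auc(score, y[te]))
    pooled = sum(per_fold, ConfusionCounts())
    m = compute_metrics(pooled)
    return ClassifierReport(
        per_fold=per_fold,
        fold_auc=fold_auc,
        pooled=pooled,
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        auc=float(np.nanmean(fold_auc)),
        seed=seed,
        fold_assignment=assignment,
    )
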
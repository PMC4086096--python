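"""Evaluation protocol: metrics, max-F thresholding, repeated CV, hold-out.

The protocol mirrors how interaction classifiers are customarily validated on
balanced positive/negative pair sets: stratified 10-fold cross-validation
repeated with fresh fold assignments to get a mean and standard deviation per
metric; the classification threshold is the probability cutoff maximizing the
F-score on the pooled out-of-fold predictions; an independent hold-out half is
scored once, at the mean of the CV-selected thresholds.

Ranking metrics (AUROC as the Mann-Whitney concordance with ties counted 1/2,
AUPR as step-wise average precision) are delegated to scikit-learn; the
confusion-table metrics and the R^2 readout (squared Pearson correlation
between predicted probability and 0/1 label) are computed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import model as model_mod
from .errors import DdicpiError, UndefinedMetricError, ValidationError


def _check_scores_labels(scores, labels, need_both=True):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-D and equal length")
    classes = set(np.unique(labels))
    if not classes <= {0, 1}:
        raise ValidationError("labels must be 0/1")
    if need_both and classes != {0, 1}:
        raise UndefinedMetricError("metric undefined with a single class")
    return scores, labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve (concordance probability, ties count 1/2)."""
    scores, labels = _check_scores_labels(scores, labels)
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    scores, labels = _check_scores_labels(scores, labels, need_both=False)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPR undefined with no positives")
    return float(average_precision_score(labels, scores))


def pseudo_r2(scores, labels) -> float:
    """Squared Pearson correlation between scores and 0/1 labels.

    Constant scores (or constant labels) return 0 by convention.
    """
    scores, labels = _check_scores_labels(scores, labels, need_both=False)
    if np.std(scores) == 0 or np.std(labels) == 0:
        return 0.0
    return float(np.corrcoef(scores, labels)[0, 1] ** 2)


@dataclass
class MetricSet:
    """One evaluation snapshot: ranking metrics plus confusion metrics at a
    single probability threshold (predict positive when score >= threshold)."""

    auroc: float
    aupr: float
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    r2: float
    threshold: float
    f1: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(scores, labels, threshold: float) -> MetricSet:
    """All metrics at one threshold, from a single confusion table."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    accuracy = (tp + tn) / len(labels)
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    return MetricSet(
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        r2=pseudo_r2(scores, labels),
        threshold=float(threshold),
        f1=f1,
    )


def max_f_threshold(scores, labels) -> tuple[float, MetricSet]:
    """Threshold (among the unique scores) maximizing the F-score.

    Ties in F are broken toward the lowest threshold.  Returns the threshold
    and the full MetricSet computed at it.
    """
    scores, labels = _check_scores_labels(scores, labels)
    best_t, best_f = None, -1.0
    for t in np.unique(scores):  # ascending, so ties keep the lowest
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1))
        denom = 2 * tp + fp + fn
        f = 2 * tp / denom if denom else 0.0
        if f > best_f:
            best_f, best_t = f, float(t)
    return best_t, confusion_metrics(scores, labels, best_t)


# ---------------------------------------------------------------------------
# repeated cross-validation and hold-out
# ---------------------------------------------------------------------------

METRIC_FIELDS = (
    "auroc", "aupr", "accuracy", "precision", "sensitivity", "specificity", "r2"
)


@dataclass
class CVReport:
    """Per-repeat metrics with their mean/sd aggregation and configuration."""

    per_repeat: list[MetricSet]
    thresholds: list[float]
    k_folds: int
    n_repeats: int
    lam: float
    base_seed: int
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            for m in METRIC_FIELDS:
                vals = np.array([getattr(r, m) for r in self.per_repeat])
                self.mean[m] = float(vals.mean())
                self.sd[m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    @property
    def mean_threshold(self) -> float:
        return float(np.mean(self.thresholds))

    def to_dict(self) -> dict:
        return {
            "config": {
                "k_folds": self.k_folds,
                "n_repeats": self.n_repeats,
                "lambda": self.lam,
                "base_seed": self.base_seed,
            },
            "per_repeat": [r.to_dict() for r in self.per_repeat],
            "thresholds": self.thresholds,
            "mean": self.mean,
            "sd": self.sd,
        }

    def to_json(self, path: str | Path) -> None:
        with open(Path(path), "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary_tsv(self) -> str:
        """One-row TSV summary in the customary column order."""
        header = "Accuracy\tPrecision\tSensitivity\tSpecificity\tAUROC\tAUPR\tR2"
        order = (
            "accuracy", "precision", "sensitivity", "specificity",
            "auroc", "aupr", "r2",
        )
        row = "\t".join(
            f"{self.mean[m]:.3f} ± {self.sd[m]:.3f}" for m in order
        )
        return header + "\n" + row + "\n"


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    repeats: int = 100,
    lam: float = 1.0,
    base_seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold cross-validation.

    Repeat r uses seed ``base_seed + r`` for its fold assignment.  Within a
    repeat the out-of-fold probabilities are pooled, the threshold is chosen
    by :func:`max_f_threshold` on the pooled scores, and one MetricSet is
    recorded per repeat.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise DdicpiError(
            f"smallest class has {counts.min()} members; cannot stratify "
            f"into {k} folds"
        )
    per_repeat: list[MetricSet] = []
    thresholds: list[float] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=base_seed + r)
        pooled = np.empty(len(y))
        for train_idx, test_idx in skf.split(X, y):
            m = model_mod.train(X[train_idx], y[train_idx], lam=lam)
            pooled[test_idx] = model_mod.predict_proba(m, X[test_idx])
        t, metrics = max_f_threshold(pooled, y)
        thresholds.append(t)
        per_repeat.append(metrics)
    return CVReport(
        per_repeat=per_repeat,
        thresholds=thresholds,
        k_folds=k,
        n_repeats=repeats,
        lam=lam,
        base_seed=base_seed,
    )


def holdout_validate(
    X: np.ndarray,
    y: np.ndarray,
    holdout_fraction: float = 0.5,
    k: int = 10,
    repeats: int = 100,
    lam: float = 1.0,
    seed: int = 0,
) -> tuple[MetricSet, CVReport]:
    """Hold-out validation with CV-averaged thresholds.

    Splits the data into a stratified training part and hold-out part, runs
    :func:`repeated_cv` on the training part, trains the final model on the
    full training part, and scores the hold-out at the MEAN of the thresholds
    selected across CV repeats.  Returns the hold-out MetricSet and the inner
    CVReport.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    idx_train, idx_hold = train_test_split(
        np.arange(len(y)),
        test_size=holdout_fraction,
        stratify=y,
        random_state=seed,
    )
    cv = repeated_cv(
        X[idx_train], y[idx_train], k=k, repeats=repeats, lam=lam, base_seed=seed
    )
    final = model_mod.train(X[idx_train], y[idx_train], lam=lam)
    hold_scores = model_mod.predict_proba(final, X[idx_hold])
    metrics = confusion_metrics(hold_scores, y[idx_hold], cv.mean_threshold)
    return metrics, cv
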
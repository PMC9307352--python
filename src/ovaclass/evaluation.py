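"""Confusion-matrix metrics, MSE, stratified k-fold CV, and a table audit.

The nine-metric report derives everything from TP/TN/FP/FN counts:
accuracy, precision, F1 and the error rate, Jaccard metric and
classification success index (CSI = PPV + SEN - 100) on the percent scale;
the Matthews correlation coefficient and Fowlkes-Mallows index as unitless
values; plus the mean squared error of the continuous scores against the
0.9/0.1 encoded targets.  Metrics are stored at full precision; printing
rounds to 3 decimals.  Any metric whose denominator vanishes is reported
as 0 and listed in ``flags``.

Cross-validation is stratified 10-fold by default (90% train / 10% test per
fold); all model fitting — gene selection, feature extraction, feature
selection, classifier — happens inside each training fold, and confusion
counts are pooled over the test folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Protocol, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledExpressionMatrix
from .errors import ConfigurationError, DataError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "CVResult",
    "metrics_from_confusion",
    "mse_scores",
    "stratified_folds",
    "stratified_kfold_cv",
    "audit_metric_table",
    "Discrepancy",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = (
    "accuracy",
    "precision",
    "f1",
    "mcc",
    "fm",
    "error_rate",
    "jaccard",
    "csi",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts (cancer = positive class)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be a non-negative count")
        if self.total == 0:
            raise ConfigurationError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ConfigurationError("y_true and y_pred lengths differ")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def _round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (tables print 57.8125 as 57.813)."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("1." + "0" * ndigits), ROUND_HALF_UP)
    )


@dataclass
class MetricsReport:
    """Nine-metric report; percent metrics on the 0-100 scale."""

    accuracy: float
    precision: float
    f1: float
    mcc: float
    fm: float
    error_rate: float
    jaccard: float
    csi: float
    mse: float | None = None
    flags: list[str] = field(default_factory=list)

    def rounded(self) -> dict[str, float | None]:
        """Values rounded half-up to 3 decimals, the printing convention."""
        out: dict[str, float | None] = {
            k: _round_half_up(getattr(self, k)) for k in METRIC_COLUMNS
        }
        out["mse"] = None if self.mse is None else float(self.mse)
        return out


def metrics_from_confusion(c: ConfusionMatrix, mse: float | None = None) -> MetricsReport:
    """Derive the nine-metric report from confusion counts.

    accuracy = 100 (TP+TN)/total, precision = 100 TP/(TP+FP),
    F1 = 100 * 2TP/(2TP+FP+FN), MCC = (TP TN - FP FN)/sqrt(prod of margins),
    FM = sqrt(PPV * TPR), error = 100 (FP+FN)/total,
    Jaccard = 100 TP/(TP+FP+FN), CSI = PPV + SEN - 100 (percent scale).
    Zero denominators yield 0 with a flag.
    """
    flags: list[str] = []

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    total = c.total
    accuracy = 100.0 * (c.tp + c.tn) / total
    error_rate = 100.0 * (c.fp + c.fn) / total
    precision = 100.0 * _ratio(c.tp, c.tp + c.fp, "precision")
    sensitivity = 100.0 * _ratio(c.tp, c.tp + c.fn, "sensitivity")
    f1 = 100.0 * _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if mcc_den == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / mcc_den
    fm = math.sqrt((precision / 100.0) * (sensitivity / 100.0))
    jaccard = 100.0 * _ratio(c.tp, c.tp + c.fp + c.fn, "jaccard")
    csi = precision + sensitivity - 100.0
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        f1=f1,
        mcc=mcc,
        fm=fm,
        error_rate=error_rate,
        jaccard=jaccard,
        csi=csi,
        mse=mse,
        flags=flags,
    )


def mse_scores(scores: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error between continuous scores and encoded targets."""
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if scores.shape != targets.shape:
        raise ConfigurationError("scores and targets lengths differ")
    return float(np.mean((scores - targets) ** 2))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldOutcome:
    """What a pipeline produces for one held-out fold."""

    scores: np.ndarray
    pred_labels: np.ndarray
    true_labels: np.ndarray
    targets: np.ndarray


class FoldRunner(Protocol):
    """Anything that can fit on a training fold and score the test fold."""

    def run_fold(
        self,
        data: LabeledExpressionMatrix,
        train_idx: np.ndarray,
        test_idx: np.ndarray,
        seed: int,
    ) -> FoldOutcome: ...


@dataclass
class CVResult:
    """Per-fold and pooled confusion matrices with metric reports."""

    fold_confusions: list[ConfusionMatrix]
    pooled_confusion: ConfusionMatrix
    pooled_metrics: MetricsReport
    mean_fold_metrics: MetricsReport
    mse: float
    fold_assignment: list[np.ndarray]
    seed: int

    @property
    def k(self) -> int:
        return len(self.fold_confusions)


def stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified partition into k (train, test) index pairs."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise DataError(
            f"smallest class has {counts.min()} samples < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return [
        (train.astype(int), test.astype(int))
        for train, test in skf.split(np.zeros(labels.size), labels)
    ]


def _mean_metrics(per_fold: Sequence[MetricsReport], mse: float) -> MetricsReport:
    vals = {
        k: float(np.mean([getattr(m, k) for m in per_fold])) for k in METRIC_COLUMNS
    }
    flags = sorted({f for m in per_fold for f in m.flags})
    return MetricsReport(mse=mse, flags=flags, **vals)


def stratified_kfold_cv(
    pipeline_config: FoldRunner,
    data: LabeledExpressionMatrix,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Run seeded stratified k-fold CV of a pipeline over ``data``.

    For every fold the runner fits everything on the training 90% and
    scores the held-out 10%; confusion counts are pooled across folds, and
    the MSE is averaged over folds.
    """
    folds = stratified_folds(data.labels, k, seed)
    fold_confusions: list[ConfusionMatrix] = []
    fold_metrics: list[MetricsReport] = []
    fold_mse: list[float] = []
    assignment: list[np.ndarray] = []
    for fold_no, (train_idx, test_idx) in enumerate(folds):
        outcome = pipeline_config.run_fold(data, train_idx, test_idx, seed + fold_no)
        cm = ConfusionMatrix.from_labels(outcome.true_labels, outcome.pred_labels)
        m = mse_scores(outcome.scores, outcome.targets)
        fold_confusions.append(cm)
        fold_metrics.append(metrics_from_confusion(cm, mse=m))
        fold_mse.append(m)
        assignment.append(test_idx)
    pooled = fold_confusions[0]
    for cm in fold_confusions[1:]:
        pooled = pooled + cm
    mean_mse = float(np.mean(fold_mse))
    return CVResult(
        fold_confusions=fold_confusions,
        pooled_confusion=pooled,
        pooled_metrics=metrics_from_confusion(pooled, mse=mean_mse),
        mean_fold_metrics=_mean_metrics(fold_metrics, mean_mse),
        mse=mean_mse,
        fold_assignment=assignment,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Table audit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Discrepancy:
    row: int
    column: str
    derived: float
    printed: float

    @property
    def delta(self) -> float:
        return abs(self.derived - self.printed)


def audit_metric_table(
    confusions: Sequence[ConfusionMatrix],
    printed_metrics: Sequence[dict],
    percent_tol: float = 0.001,
    coef_tol: float = 0.0005,
) -> list[Discrepancy]:
    """Recompute metrics from confusion counts and diff against printed rows.

    ``printed_metrics`` rows are dicts keyed by metric column (missing
    columns are skipped).  Percent-scale metrics are compared at
    ``percent_tol`` after rounding to 3 decimals; mcc and fm at
    ``coef_tol``.
    """
    if len(confusions) != len(printed_metrics):
        raise ConfigurationError("confusions and printed_metrics must pair up")
    out: list[Discrepancy] = []
    for i, (cm, printed) in enumerate(zip(confusions, printed_metrics)):
        derived = metrics_from_confusion(cm).rounded()
        for col in METRIC_COLUMNS:
            if col not in printed or printed[col] is None:
                continue
            tol = coef_tol if col in ("mcc", "fm") else percent_tol
            if abs(derived[col] - printed[col]) > tol:
                out.append(
                    Discrepancy(row=i, column=col, derived=derived[col], printed=printed[col])
                )
    return out
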
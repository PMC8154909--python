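"""Evaluation statistics for measurement models.

Regression tasks are scored with MAE and RMSE against a ZeroR reference
(the predictor that always outputs the population mean of the label);
human-comparison style scoring additionally removes a rater's systematic
offset (bias-subtracted MAE) and reports Pearson's r.  Binary tasks are
scored with threshold-0.5 accuracy and rank-based AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["mae", "rmse", "zeror", "bias_subtracted_mae", "pearson_r",
           "classification_metrics", "EvalReport"]


def _pair(predicted, actual) -> Tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty input")
    if p.size != a.size:
        raise ValueError(f"length mismatch: {p.size} vs {a.size}")
    return p, a


def mae(predicted, actual) -> float:
    """Mean absolute error, mean(|predicted - actual|)."""
    p, a = _pair(predicted, actual)
    return float(np.mean(np.abs(p - a)))


def rmse(predicted, actual) -> float:
    """Root-mean-squared error; more sensitive to outliers than MAE."""
    p, a = _pair(predicted, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def zeror(actual) -> Tuple[float, float]:
    """(MAE, RMSE) of the constant-mean predictor, from labels alone.

    The ZeroR RMSE equals the uncorrected standard deviation of the
    labels.
    """
    a = np.asarray(actual, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty input")
    m = a.mean()
    return mae(np.full_like(a, m), a), rmse(np.full_like(a, m), a)


def bias_subtracted_mae(predicted, actual) -> Tuple[float, float]:
    """(bias, MAE*) where bias = mean(actual - predicted).

    The bias is the rater's average offset from the ground truth; MAE* is
    the MAE after adding that offset back to the predictions, so a rater
    who is consistently shifted by a constant scores MAE* = 0.
    """
    p, a = _pair(predicted, actual)
    bias = float(np.mean(a - p))
    return bias, mae(p + bias, a)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation in [-1, 1]."""
    xv, yv = _pair(x, y)
    if xv.size < 2:
        raise ValueError("pearson_r needs at least 2 points")
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))


def classification_metrics(prob, label) -> Tuple[float, float]:
    """(accuracy at threshold 0.5, rank-based AUC with half-credit ties).

    The AUC is the Mann-Whitney statistic: ties between a positive and a
    negative score count half, so an uninformative constant score gives
    exactly 0.5.
    """
    p, y = _pair(prob, label)
    uy = np.unique(y)
    if not np.all(np.isin(uy, [0.0, 1.0])):
        raise ValueError("labels must be binary 0/1")
    if uy.size < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    acc = float(np.mean((p >= 0.5) == (y == 1.0)))
    n1 = int(np.sum(y == 1.0))
    n0 = y.size - n1
    ranks = rankdata(p)          # average ranks implement half-credit ties
    auc = (ranks[y == 1.0].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return acc, float(auc)


@dataclass
class EvalReport:
    """Per-fold evaluation of one task, with fold mean +/- SD aggregation.

    Fold SD uses the n-1 denominator.  ZeroR columns are computed from the
    validation labels only.
    """

    task: str
    kind: str                           # "regression" | "classification"
    n: int = 0
    fold_mae: List[float] = field(default_factory=list)
    fold_rmse: List[float] = field(default_factory=list)
    fold_acc: List[float] = field(default_factory=list)
    fold_auc: List[float] = field(default_factory=list)
    zeror_mae: Optional[float] = None
    zeror_rmse: Optional[float] = None

    @staticmethod
    def _agg(vals: List[float]) -> Tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    @property
    def mae_mean(self) -> float:
        return self._agg(self.fold_mae)[0]

    @property
    def mae_sd(self) -> float:
        return self._agg(self.fold_mae)[1]

    @property
    def rmse_mean(self) -> float:
        return self._agg(self.fold_rmse)[0]

    @property
    def acc_mean(self) -> float:
        return self._agg(self.fold_acc)[0]

    @property
    def auc_mean(self) -> float:
        return self._agg(self.fold_auc)[0]

    def add_regression_fold(self, predicted, actual) -> None:
        self.fold_mae.append(mae(predicted, actual))
        self.fold_rmse.append(rmse(predicted, actual))
        self.n += len(np.asarray(actual).ravel())

    def add_classification_fold(self, prob, label) -> None:
        acc, auc = classification_metrics(prob, label)
        self.fold_acc.append(acc)
        self.fold_auc.append(auc)
        self.n += len(np.asarray(label).ravel())

    def to_frame(self) -> pd.DataFrame:
        if self.kind == "regression":
            row = {"task": self.task, "n": self.n,
                   "MAE": self.mae_mean, "MAE_sd": self.mae_sd,
                   "RMSE": self.rmse_mean, "RMSE_sd": self._agg(self.fold_rmse)[1],
                   "ZeroR_MAE": self.zeror_mae, "ZeroR_RMSE": self.zeror_rmse}
        else:
            row = {"task": self.task, "n": self.n,
                   "ACC": self.acc_mean, "ACC_sd": self._agg(self.fold_acc)[1],
                   "AUC": self.auc_mean, "AUC_sd": self._agg(self.fold_auc)[1]}
        return pd.DataFrame([row])
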
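"""Regression error metrics for affinity prediction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MetricReport", "evaluate_metrics"]


@dataclass(frozen=True)
class MetricReport:
    """The five error metrics used to judge affinity regressions."""

    rmse: float
    mae: float
    r2: float
    pearson: float
    spearman: float

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "mae": self.mae, "r2": self.r2,
                "pearson": self.pearson, "spearman": self.spearman}


def evaluate_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricReport:
    """RMSE, MAE, R^2, Pearson and Spearman (average ranks on ties).

    With zero-variance targets the correlation coefficients are undefined
    and reported as NaN with a warning.
    """
    y = np.asarray(y_true, dtype=np.float64).ravel()
    yhat = np.asarray(y_pred, dtype=np.float64).ravel()
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("predictions and targets must be equal-length, non-empty")
    err = yhat - y
    rmse = float(np.sqrt((err**2).mean()))
    mae = float(np.abs(err).mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0 or np.std(yhat) == 0.0:
        if ss_tot == 0.0:
            warnings.warn("zero-variance targets: R2/Pearson/Spearman undefined")
            return MetricReport(rmse, mae, np.nan, np.nan, np.nan)
        warnings.warn("zero-variance predictions: Pearson/Spearman undefined")
        return MetricReport(rmse, mae, 1.0 - (err**2).sum() / ss_tot, np.nan, np.nan)
    r2 = 1.0 - float((err**2).sum()) / ss_tot
    pearson = float(stats.pearsonr(y, yhat).statistic)
    spearman = float(stats.spearmanr(y, yhat).statistic)
    return MetricReport(rmse, mae, r2, pearson, spearman)
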
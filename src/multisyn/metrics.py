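"""Regression and classification metrics with per-fold aggregation.

Regression: MSE, RMSE and Pearson correlation on the Loewe score scale.
Classification follows the screen's reporting convention: the model is
trained three-class (antagonistic / additive / synergistic) but threshold
metrics are evaluated on the binary antagonistic-vs-synergistic subset —
additive samples are excluded — using P(synergistic) as the ranking score.

Per-fold values are aggregated as mean ± sample SD with a Student-t 95 %
confidence interval, mean ± t_{0.975, n-1} * sd / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    cohen_kappa_score,
    precision_score,
    roc_auc_score,
)

from .data_pipeline import ANTAGONISTIC, SYNERGISTIC

__all__ = [
    "MetricReport",
    "regression_metrics",
    "classification_metrics",
    "ci_from_stats",
    "fold_aggregate_ci",
]


@dataclass(frozen=True)
class MetricReport:
    """Across-fold summary of one metric."""

    name: str
    values: tuple[float, ...]
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def n_folds(self) -> int:
        return len(self.values)


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """MSE, RMSE and Pearson correlation.

    With a zero-variance argument the correlation is undefined; it is
    reported as NaN together with ``pearson_defined = False``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length, non-empty")
    mse = float(np.mean((y - yhat) ** 2))
    out = {"mse": mse, "rmse": float(np.sqrt(mse))}
    if np.std(y) == 0.0 or np.std(yhat) == 0.0:
        out["pearson"] = float("nan")
        out["pearson_defined"] = False
    else:
        out["pearson"] = float(stats.pearsonr(y, yhat).statistic)
        out["pearson_defined"] = True
    return out


def classification_metrics(y_true: np.ndarray, probs: np.ndarray) -> dict[str, float]:
    """Binary synergy metrics on the antagonistic/synergistic subset.

    ``y_true`` holds three-class labels; ``probs`` the (n, 3) class
    probabilities. Rows whose true class is additive are dropped. The hard
    binary prediction is argmax over the three classes mapped to
    "synergistic vs not"; ranking metrics use P(synergistic). With a
    single-class truth the AUCs are undefined and reported as NaN with
    ``auc_defined = False``.
    """
    y_true = np.asarray(y_true)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != y_true.shape[0]:
        raise ValueError("probs must be (n_samples, n_classes)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    mask = (y_true == ANTAGONISTIC) | (y_true == SYNERGISTIC)
    if not mask.any():
        # nothing but additive samples: every binary metric is undefined
        return {"accuracy": float("nan"), "precision": float("nan"),
                "kappa": float("nan"), "n_eval": 0, "roc_auc": float("nan"),
                "pr_auc": float("nan"), "auc_defined": False}
    yb = (y_true[mask] == SYNERGISTIC).astype(int)
    score = probs[mask, SYNERGISTIC]
    pred = (np.argmax(probs[mask], axis=1) == SYNERGISTIC).astype(int)
    out = {
        "accuracy": float(accuracy_score(yb, pred)),
        "precision": float(precision_score(yb, pred, zero_division=0)),
        "kappa": float(cohen_kappa_score(yb, pred)),
        "n_eval": int(mask.sum()),
    }
    if len(np.unique(yb)) < 2:
        out.update(roc_auc=float("nan"), pr_auc=float("nan"), auc_defined=False)
    else:
        out.update(
            roc_auc=float(roc_auc_score(yb, score)),
            pr_auc=float(average_precision_score(yb, score)),
            auc_defined=True,
        )
    return out


def ci_from_stats(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval from an across-fold mean and sample SD."""
    if n < 2:
        raise ValueError("confidence interval needs n >= 2 folds")
    half = stats.t.ppf(0.5 + level / 2.0, df=n - 1) * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def fold_aggregate_ci(values, name: str = "metric", level: float = 0.95) -> MetricReport:
    """Aggregate per-fold metric values into mean, sample SD and t-CI."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 fold values to aggregate")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    lo, hi = ci_from_stats(mean, sd, vals.size, level)
    return MetricReport(name, tuple(float(v) for v in vals), mean, sd, lo, hi, level)
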
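"""Regression evaluation metrics: concordance index, MSE, rm2, AUPR.

Conventions for affinity regression:

* CI counts pairs with distinct true values; a prediction tie scores 0.5.
  1 = perfect ranking, 0 = inverted, 0.5 = chance.
* rm2 = r^2 * (1 - sqrt(|r^2 - r0^2|)) with r^2 the squared Pearson
  correlation and r0^2 the squared correlation of the least-squares fit of
  predictions on observations through the origin.
* AUPR binarizes true affinities at a dataset-style threshold (pKd >= 7
  for Kd-style data, 12.1 for KIBA scores) and integrates the
  precision-recall curve step-wise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

AUPR_THRESHOLDS = {"Kd": 7.0, "Ki": 7.0, "KIBA": 12.1, "pre-transformed": 7.0, "IC50": 7.0}


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. all labels tied)."""


def _check(y_true, y_pred, min_len=1):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < min_len:
        raise UndefinedMetricError(f"need at least {min_len} observations")
    return y_true, y_pred


def concordance_index(y_true, y_pred) -> float:
    """Fraction of correctly ordered prediction pairs (ties score 0.5)."""
    y_true, y_pred = _check(y_true, y_pred, min_len=2)
    dt = y_true[:, None] - y_true[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    comparable = dt > 0  # ordered pairs (i, j) with y_true[i] > y_true[j]
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise UndefinedMetricError("all true values tied: CI undefined")
    wins = (dp[comparable] > 0).sum() + 0.5 * (dp[comparable] == 0).sum()
    return float(wins / n_pairs)


def mse(y_true, y_pred) -> float:
    y_true, y_pred = _check(y_true, y_pred)
    return float(np.mean((y_true - y_pred) ** 2))


def rm2(y_true, y_pred) -> float:
    """QSAR external-validation metric penalizing r^2 by the through-origin gap."""
    y_true, y_pred = _check(y_true, y_pred, min_len=3)
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise UndefinedMetricError("zero variance: rm2 undefined")
    r = np.corrcoef(y_true, y_pred)[0, 1]
    r2 = r * r
    # least-squares slope through the origin of y_pred = k * y_true
    k = np.dot(y_true, y_pred) / np.dot(y_true, y_true)
    ss_res = np.sum((y_pred - k * y_true) ** 2)
    ss_tot = np.sum((y_pred - np.mean(y_pred)) ** 2)
    r0_2 = 1.0 - ss_res / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r0_2))))


def aupr(y_true, y_pred, threshold: float = 7.0) -> float:
    """Area under the precision-recall curve after binarizing at ``threshold``."""
    y_true, y_pred = _check(y_true, y_pred, min_len=2)
    labels = (y_true >= threshold).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("one class after binarization: AUPR undefined")
    return float(average_precision_score(labels, y_pred))


@dataclass
class MetricsReport:
    """Aggregate (mean over folds) plus per-fold values and dispersion."""

    ci: float
    mse: float
    rm2: float
    aupr: float
    per_fold: list[dict] = field(default_factory=list)
    n_pairs_ci: int = 0

    @property
    def std(self) -> dict:
        out = {}
        for key in ("ci", "mse", "rm2", "aupr"):
            vals = [f[key] for f in self.per_fold if f.get(key) is not None]
            out[key] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return out

    def to_dict(self) -> dict:
        return {
            "ci": self.ci, "mse": self.mse, "rm2": self.rm2, "aupr": self.aupr,
            "std": self.std, "per_fold": self.per_fold, "n_pairs_ci": self.n_pairs_ci,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def evaluate_fold(y_true, y_pred, aupr_threshold: float = 7.0) -> dict:
    """All four metrics for one fold; undefined ones are reported as None."""
    fold = {}
    for name, fn in (
        ("ci", concordance_index),
        ("mse", mse),
        ("rm2", rm2),
        ("aupr", lambda t, p: aupr(t, p, aupr_threshold)),
    ):
        try:
            fold[name] = fn(y_true, y_pred)
        except UndefinedMetricError:
            fold[name] = None
    y_true = np.asarray(y_true, dtype=float)
    fold["n"] = int(y_true.size)
    return fold


def aggregate_folds(per_fold: list[dict]) -> MetricsReport:
    """Mean of per-fold metrics, skipping folds where a metric was undefined."""
    def _mean(key):
        vals = [f[key] for f in per_fold if f.get(key) is not None]
        return float(np.mean(vals)) if vals else float("nan")

    n_pairs = sum(f.get("n", 0) * (f.get("n", 0) - 1) // 2 for f in per_fold)
    return MetricsReport(
        ci=_mean("ci"), mse=_mean("mse"), rm2=_mean("rm2"), aupr=_mean("aupr"),
        per_fold=per_fold, n_pairs_ci=n_pairs,
    )
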
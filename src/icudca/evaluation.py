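"""Discrimination and calibration metrics for predicted exit probabilities.

Covers ROC AUC, precision-recall AUC, Brier score, F1 at a fixed 0.5
threshold, logistic recalibration (intercept and slope), and 20-bin
reliability tables. An intercept of 0 and slope of 1 indicate perfect
calibration; slope < 1 means the predictions are too extreme (overconfident),
slope > 1 too compressed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from sklearn.metrics import average_precision_score, brier_score_loss, f1_score, roc_auc_score

from .errors import UndefinedMetricError

__all__ = [
    "CalibrationReport",
    "discrimination",
    "recalibrate",
    "brier",
    "f1_at",
    "reliability_bins",
    "summarize",
]

#: probabilities are clipped to [EPS, 1-EPS] before the logit transform
EPS = 1e-6


def _check(y, p) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.size == 0:
        raise UndefinedMetricError("empty prediction set")
    if y.shape != p.shape:
        raise ValueError("y and p must be aligned")
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must be finite and in [0, 1]")
    return y, p


def discrimination(y, p) -> tuple[float, float]:
    """ROC AUC and precision-recall AUC.

    ROC AUC is the probability a random positive outscores a random negative
    (ties counted half). PR AUC uses the step-wise (non-interpolated)
    average-precision estimator. Raises
    :class:`~icudca.errors.UndefinedMetricError` when only one class is
    present.
    """
    y, p = _check(y, p)
    if np.unique(y).size < 2:
        raise UndefinedMetricError("both classes required for discrimination metrics")
    return float(roc_auc_score(y, p)), float(average_precision_score(y, p))


def recalibrate(y, p, eps: float = EPS) -> tuple[float, float]:
    """Calibration intercept and slope by logistic recalibration.

    Fits ``logit P(y=1) = a + b * logit(p)`` by maximum likelihood and
    returns ``(a, b)``. Perfectly calibrated predictions give (0, 1) in
    large samples. Degenerate inputs (constant predictions, single-class
    outcomes, non-convergence) raise rather than silently defaulting.
    """
    y, p = _check(y, p)
    if np.unique(y).size < 2:
        raise UndefinedMetricError("both classes required for recalibration")
    lp = logit(np.clip(p, eps, 1 - eps))
    if np.ptp(lp) == 0:
        raise UndefinedMetricError("recalibration slope undefined for constant predictions")
    X = sm.add_constant(lp)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    if not np.all(np.isfinite(res.params)):
        raise UndefinedMetricError("logistic recalibration did not converge")
    a, b = res.params
    return float(a), float(b)


def brier(y, p) -> float:
    """Mean squared error between predicted probability and outcome."""
    y, p = _check(y, p)
    return float(brier_score_loss(y, p))


def f1_at(y, p, t: float = 0.5) -> float:
    """F1 score after binarizing predictions at threshold ``t`` (p >= t)."""
    y, p = _check(y, p)
    return float(f1_score(y.astype(int), (p >= t).astype(int)))


def reliability_bins(y, p, k: int = 20) -> pd.DataFrame:
    """Reliability table over ``k`` equal-width probability bins.

    Columns: ``bin_lo``, ``bin_hi``, ``mean_pred``, ``obs_rate``, ``count``.
    Empty bins are kept with NaN rates so the table always has ``k`` rows and
    the counts sum to ``len(y)``.
    """
    y, p = _check(y, p)
    edges = np.linspace(0.0, 1.0, k + 1)
    which = np.clip(np.floor(p * k).astype(int), 0, k - 1)
    rows = []
    for b in range(k):
        sel = which == b
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "mean_pred": float(p[sel].mean()) if n else np.nan,
                "obs_rate": float(y[sel].mean()) if n else np.nan,
                "count": n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CalibrationReport:
    """Bundle of the discrimination and calibration metrics for one model."""

    roc_auc: float
    pr_auc: float
    brier: float
    f1_at_05: float
    calibration_intercept: float
    calibration_slope: float
    n: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def summarize(y, p) -> CalibrationReport:
    """Compute the full metric bundle for one prediction set."""
    y, p = _check(y, p)
    roc, pr = discrimination(y, p)
    a, b = recalibrate(y, p)
    return CalibrationReport(
        roc_auc=roc,
        pr_auc=pr,
        brier=brier(y, p),
        f1_at_05=f1_at(y, p),
        calibration_intercept=a,
        calibration_slope=b,
        n=int(y.size),
    )
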
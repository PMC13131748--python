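"""Decision curve analysis for threshold-based review policies.

Acting on a prediction here means initiating proactive chart review for a
patient-day flagged as likely to exit the ICU tomorrow. Net benefit at a
threshold probability t is

    NB(t) = TP/N - (FP/N) * t / (1 - t)

so a false positive costs w = t/(1-t) true-positive units: the threshold
itself encodes how many unnecessary reviews one is willing to perform to
avoid missing one true next-day exit. Model-guided flagging is compared to
reviewing every patient-day (treat-all), reviewing none (net benefit
identically 0), and a simple physiologic-stability heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "fp_penalty_weight",
    "net_benefit",
    "HeuristicRule",
    "heuristic_flags",
    "decision_curve",
    "default_grid",
]


def _check_threshold(t: float) -> float:
    t = float(t)
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie strictly in (0, 1); got {t}")
    return t


def fp_penalty_weight(t: float) -> float:
    """Implied relative cost of a false positive at threshold ``t``.

    w = t / (1 - t): the number of unnecessary reviews considered an
    acceptable price for avoiding one missed next-day exit. Strictly
    increasing in t; e.g. t=0.5 -> 1 (one-for-one), t=0.9 -> 9.
    """
    t = _check_threshold(t)
    return t / (1.0 - t)


def net_benefit(tp: float, fp: float, n: float, t: float) -> float:
    """Net benefit of a review policy with ``tp``/``fp`` counts among ``n`` days."""
    t = _check_threshold(t)
    if n <= 0:
        raise ValueError("n must be positive")
    if tp + fp > n + 1e-9:
        raise ValueError("tp + fp cannot exceed n")
    return tp / n - (fp / n) * fp_penalty_weight(t)


@dataclass(frozen=True)
class HeuristicRule:
    """Physiologic stability screen used as the non-model baseline.

    A patient-day is flagged for review when the daily heart-rate summary is
    below ``hr_threshold``, the respiratory-rate summary below
    ``rr_threshold``, and no vasopressor ran in the prior 24 h (day-level
    vasopressor indicator). Summary columns are configurable; the daily mean
    is the default since the feature set carries min/mean/SD summaries. Any
    missing component leaves the day unflagged, to avoid inflating the
    baseline's apparent sensitivity.
    """

    hr_threshold: float = 100.0
    rr_threshold: float = 28.0
    hr_col: str = "heart_rate_mean"
    rr_col: str = "resp_rate_mean"
    vaso_col: str = "vasopressor_flag"


def heuristic_flags(table: pd.DataFrame, rule: HeuristicRule = HeuristicRule()) -> np.ndarray:
    """Deterministic boolean review flag per patient-day row."""
    hr = table[rule.hr_col].to_numpy(dtype=float)
    rr = table[rule.rr_col].to_numpy(dtype=float)
    vaso = table[rule.vaso_col].to_numpy(dtype=float)
    # NaN comparisons are False, so missing components never flag
    with np.errstate(invalid="ignore"):
        return (hr < rule.hr_threshold) & (rr < rule.rr_threshold) & (vaso == 0)


def default_grid() -> np.ndarray:
    """Threshold grid 0.01 .. 0.99 in steps of 0.01."""
    return np.round(np.arange(1, 100) / 100.0, 2)


def _confusion(flag: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(flag & (y == 1)))
    fp = int(np.sum(flag & (y == 0)))
    fn = int(np.sum(~flag & (y == 1)))
    tn = int(np.sum(~flag & (y == 0)))
    return tp, fp, tn, fn


def decision_curve(
    y,
    p,
    heuristic: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-threshold confusion counts, strategy net benefits and workload.

    Binarization is ``p >= t`` (ties flag positive). Returns one row per
    threshold with columns ``threshold``, confusion counts ``tp fp tn fn``
    for the model strategy, net benefit for the four strategies
    (``nb_model``, ``nb_all``, ``nb_none``, ``nb_heuristic`` — NaN when no
    heuristic flags are supplied), ``flagged_fraction`` and true/false
    positives per 1,000 patient-days.
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid thresholds must lie strictly in (0, 1)")

    n = len(y)
    pos = int(np.sum(y == 1))
    neg = n - pos
    h = None
    if heuristic is not None:
        h = np.asarray(heuristic, dtype=bool)
        h_tp, h_fp, _, _ = _confusion(h, y)

    rows = []
    for t in grid:
        flag = p >= t
        tp, fp, tn, fn = _confusion(flag, y)
        rows.append(
            {
                "threshold": t,
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                "nb_model": net_benefit(tp, fp, n, t),
                "nb_all": net_benefit(pos, neg, n, t),
                "nb_none": 0.0,
                "nb_heuristic": net_benefit(h_tp, h_fp, n, t) if h is not None else np.nan,
                "flagged_fraction": (tp + fp) / n,
                "tp_per_1000": 1000.0 * tp / n,
                "fp_per_1000": 1000.0 * fp / n,
            }
        )
    return pd.DataFrame(rows)
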
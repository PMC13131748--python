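"""Operational recruitment-workflow model layered on the decision curve.

Net benefit says *whether* acting on predictions beats the baselines; this
module says whether acting is *implementable*. Threshold-specific confusion
counts are converted to rates per 100 ICU patient-days, scaled by a fixed
daily census to expected daily counts, and pushed through a research
coordinator's day:

    flagged/day   = (TP100 + FP100) * census / 100
    review min    = flagged/day * review_minutes
    eligible/day  = TP/day * eligibility_rate
    consent min   = eligible/day * consent_minutes
    total min     = review + consent            (must fit the daily budget)
    enroll/day    = eligible/day * consent_rate
    net value/day = enroll/day * v_enroll - missed_eligible/day * c_miss

All accounting is expected-value (fractional) rather than integer, matching
the deterministic daily-rate framing. A threshold is feasible when total
minutes fit the budget and flagged charts fit review capacity; among
feasible thresholds the optimizer maximizes net value when the value
parameters are supplied, otherwise enrollments/day (missed eligible patients
being the binding concern in eligibility-limited recruitment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "OpsParams",
    "per100_rates",
    "ops_table",
    "net_value",
    "days_to_target",
    "optimize_threshold",
    "sensitivity_grid",
]


@dataclass(frozen=True)
class OpsParams:
    """Workflow constants for the recruitment model.

    Times are minutes, the census is patient-days per calendar day, and the
    value parameters are in arbitrary currency. ``v_enroll`` and ``c_miss``
    carry no defaults: net value is only computed when a user supplies both.
    ``max_daily_reviews`` defaults to the census (one can at most review
    every chart once).
    """

    census: float = 30.0
    review_minutes: float = 7.0
    consent_minutes: float = 60.0
    daily_budget: float = 480.0
    eligibility_rate: float = 0.10
    consent_rate: float = 0.60
    v_enroll: float | None = None
    c_miss: float | None = None
    enroll_target: float = 300.0
    max_daily_reviews: float | None = None

    def __post_init__(self) -> None:
        for name in ("eligibility_rate", "consent_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("census", "review_minutes", "consent_minutes", "daily_budget", "enroll_target"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def review_capacity(self) -> float:
        return self.census if self.max_daily_reviews is None else self.max_daily_reviews

    @property
    def has_value_params(self) -> bool:
        return self.v_enroll is not None and self.c_miss is not None


def per100_rates(tp: float, fp: float, fn: float, tn: float) -> tuple[float, float, float, float]:
    """Confusion counts -> rates per 100 patient-days (sum exactly 100)."""
    n = tp + fp + fn + tn
    if n <= 0:
        raise ValueError("confusion counts sum to zero")
    return tuple(100.0 * c / n for c in (tp, fp, fn, tn))


def net_value(enrollments_per_day: float, missed_per_day: float, params: OpsParams) -> float:
    """Expected daily net value of operating at a threshold.

    Requires both ``v_enroll`` and ``c_miss``; raises
    :class:`~icudca.errors.ConfigurationError` otherwise, since no defensible
    default exists for either.
    """
    if not params.has_value_params:
        raise ConfigurationError("net value requires both v_enroll and c_miss to be set")
    return enrollments_per_day * params.v_enroll - missed_per_day * params.c_miss


def days_to_target(enrollments_per_day: float, params: OpsParams) -> float:
    """Projected days to reach the enrollment target (inf at zero yield)."""
    if enrollments_per_day <= 0:
        return float("inf")
    return params.enroll_target / enrollments_per_day


def _ops_row(t: float, tp100: float, fp100: float, fn100: float, tn100: float, params: OpsParams) -> dict:
    scale = params.census / 100.0
    flagged = (tp100 + fp100) * scale
    tp_day = tp100 * scale
    fn_day = fn100 * scale
    eligible = tp_day * params.eligibility_rate
    enroll = eligible * params.consent_rate
    missed = fn_day * params.eligibility_rate
    review_min = flagged * params.review_minutes
    consent_min = eligible * params.consent_minutes
    total_min = review_min + consent_min
    feasible = (total_min <= params.daily_budget) and (flagged <= params.review_capacity)
    return {
        "threshold": t,
        "tp100": tp100,
        "fp100": fp100,
        "fn100": fn100,
        "tn100": tn100,
        "flagged_per_day": flagged,
        "tp_per_day": tp_day,
        "eligible_per_day": eligible,
        "enrollments_per_day": enroll,
        "missed_eligible_per_day": missed,
        "review_minutes": review_min,
        "consent_minutes": consent_min,
        "total_minutes": total_min,
        "feasible": feasible,
        "net_value_per_day": net_value(enroll, missed, params) if params.has_value_params else np.nan,
        "days_to_target": days_to_target(enroll, params),
    }


def ops_table(curve: pd.DataFrame, params: OpsParams) -> pd.DataFrame:
    """Per-threshold operational outcomes from a decision curve.

    ``curve`` must carry ``threshold`` and the model-strategy confusion
    counts ``tp``, ``fp``, ``fn``, ``tn`` (as produced by
    :func:`icudca.dca.decision_curve`).
    """
    if curve.empty:
        raise ValueError("empty decision curve")
    rows = []
    for rec in curve.itertuples(index=False):
        tp100, fp100, fn100, tn100 = per100_rates(rec.tp, rec.fp, rec.fn, rec.tn)
        rows.append(_ops_row(rec.threshold, tp100, fp100, fn100, tn100, params))
    return pd.DataFrame(rows)


def optimize_threshold(
    curve: pd.DataFrame, params: OpsParams
) -> tuple[float, pd.Series] | None:
    """Best feasible operating threshold, or None when none is feasible.

    Objective: net value/day when both value parameters are set, otherwise
    enrollments/day. Ties break toward lower review minutes, then lower
    threshold, so the result is deterministic.
    """
    table = ops_table(curve, params)
    feas = table[table["feasible"]]
    if feas.empty:
        return None
    objective = "net_value_per_day" if params.has_value_params else "enrollments_per_day"
    ordered = feas.sort_values(
        [objective, "review_minutes", "threshold"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    best = ordered.iloc[0]
    return float(best["threshold"]), best


def sensitivity_grid(
    curve: pd.DataFrame, params: OpsParams, sweep: dict[str, list]
) -> pd.DataFrame:
    """Cartesian sweep over workflow parameters; one row per cell.

    Each row records the swept parameter values, the optimal feasible
    threshold for that cell (NaN when nothing is feasible) and its operating
    outcomes.
    """
    if not sweep:
        raise ValueError("empty sweep specification")
    names = list(sweep)
    rows = []
    for combo in itertools.product(*(sweep[k] for k in names)):
        cell_params = replace(params, **dict(zip(names, combo)))
        cell: dict = dict(zip(names, combo))
        best = optimize_threshold(curve, cell_params)
        if best is None:
            cell.update({"opt_threshold": np.nan, "feasible_any": False})
        else:
            t, row = best
            cell.update(
                {
                    "opt_threshold": t,
                    "feasible_any": True,
                    "enrollments_per_day": row["enrollments_per_day"],
                    "missed_eligible_per_day": row["missed_eligible_per_day"],
                    "total_minutes": row["total_minutes"],
                    "net_value_per_day": row["net_value_per_day"],
                    "days_to_target": row["days_to_target"],
                }
            )
        rows.append(cell)
    return pd.DataFrame(rows)
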
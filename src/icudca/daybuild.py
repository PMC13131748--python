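"""Patient-day table -> modeling matrix: alignment, filling, imputation, splits.

All steps are leakage-free by construction: forward filling only looks
backward within an admission, median imputation statistics come from the
training partition only, and splits are performed at the admission level so
no patient contributes rows to more than one partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import feature_columns
from .errors import MalformedAdmissionError

__all__ = [
    "ImputationModel",
    "align_labels",
    "forward_fill",
    "fit_imputer",
    "apply_imputer",
    "split_admissions",
    "cv_fold_indices",
]

log = logging.getLogger(__name__)

PARTITIONS = ("train", "test", "holdout")


def align_labels(
    table: pd.DataFrame,
    min_days: int = 1,
    max_days: int = 60,
) -> pd.DataFrame:
    """Validate and filter the temporal labeling of a patient-day table.

    Checks that ``day_index`` within each admission is consecutive starting
    at 1 (raising :class:`MalformedAdmissionError` otherwise) and that no
    admission carries an exit label before its last day. Rows whose next-day
    outcome is undefined (NaN label, possible on user-supplied data) are
    dropped and counted in the log; admissions shorter than ``min_days`` or
    longer than ``max_days`` labeled days are excluded, mirroring the
    upstream cohort filters applied to real EHR extracts (sub-24 h stays,
    implausible durations).
    """
    table = table.sort_values(["admission_id", "day_index"], kind="mergesort").reset_index(
        drop=True
    )
    grp = table.groupby("admission_id", sort=False)
    day = table["day_index"].to_numpy()
    pos = grp.cumcount().to_numpy() + 1
    if not np.array_equal(day, pos):
        bad = table.loc[day != pos, "admission_id"].iloc[0]
        raise MalformedAdmissionError(
            f"admission {bad!r}: day_index not consecutive from 1"
        )

    label = table["label_exit_next_day"]
    n_undefined = int(label.isna().sum())
    if n_undefined:
        log.warning("dropping %d patient-days with undefined next-day outcome", n_undefined)
        table = table[label.notna()].reset_index(drop=True)
        table["label_exit_next_day"] = table["label_exit_next_day"].astype(np.int64)

    # exit may occur on the last labeled day only (no re-entry)
    last = table.groupby("admission_id", sort=False)["day_index"].transform("max")
    early_exit = (table["label_exit_next_day"] == 1) & (table["day_index"] < last)
    if early_exit.any():
        bad = table.loc[early_exit, "admission_id"].iloc[0]
        raise MalformedAdmissionError(f"admission {bad!r}: exit label before final day")

    n_days = table.groupby("admission_id", sort=False)["day_index"].transform("size")
    keep = (n_days >= min_days) & (n_days <= max_days)
    return table[keep].reset_index(drop=True)


def forward_fill(table: pd.DataFrame) -> pd.DataFrame:
    """Carry each feature's most recent prior observation forward in time.

    Filling never crosses admission boundaries and never looks backward in
    time (a leading absence stays absent), so a row's value depends only on
    days <= its own.
    """
    out = table.sort_values(["admission_id", "day_index"], kind="mergesort").reset_index(
        drop=True
    )
    feats = feature_columns(out)
    out[feats] = out.groupby("admission_id", sort=False)[feats].ffill()
    return out


@dataclass
class ImputationModel:
    """Training-partition medians plus the missingness-based drop list."""

    medians: dict[str, float]
    missingness: dict[str, float]
    dropped: list[str] = field(default_factory=list)


def fit_imputer(train_table: pd.DataFrame, max_missingness: float = 0.60) -> ImputationModel:
    """Fit per-feature training medians; drop features too sparse to trust.

    Features whose training missingness exceeds ``max_missingness`` (or that
    are never observed at all) are excluded from every partition rather than
    imputed. Statistics come exclusively from the table passed here, which
    must be the training partition.
    """
    feats = feature_columns(train_table)
    medians: dict[str, float] = {}
    missing: dict[str, float] = {}
    dropped: list[str] = []
    for c in feats:
        frac = float(train_table[c].isna().mean())
        missing[c] = frac
        if frac > max_missingness or frac == 1.0:
            dropped.append(c)
            if frac == 1.0:
                log.warning("feature %r never observed in training; dropped", c)
            continue
        medians[c] = float(train_table[c].median())
    return ImputationModel(medians=medians, missingness=missing, dropped=dropped)


def apply_imputer(model: ImputationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Median-impute remaining absences and drop the excluded features.

    Idempotent: applying twice equals applying once.
    """
    out = table.drop(columns=[c for c in model.dropped if c in table.columns])
    fill = {c: m for c, m in model.medians.items() if c in out.columns}
    out = out.fillna(fill)
    return out


def split_admissions(
    table: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.81, 0.09, 0.10),
    seed: int = 0,
    n_folds: int = 10,
) -> pd.DataFrame:
    """Assign every admission to train/test/holdout plus CV folds in train.

    Partition sizes follow ``fractions`` by admission count with
    largest-remainder rounding; all patient-days of an admission share its
    partition. Within the training partition, ``n_folds`` cross-validation
    folds are stratified on the admission-level indicator "ever exits to the
    hospital floor". Deterministic given ``seed``.

    Returns a frame with columns ``admission_id``, ``partition``, ``fold``
    (fold is -1 outside train).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    admissions = table["admission_id"].drop_duplicates().to_numpy()
    n = len(admissions)
    if n < n_folds:
        raise ValueError(f"{n} admissions < {n_folds} folds")
    order = rng.permutation(n)
    admissions = admissions[order]

    raw = np.array(fractions) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    for i in np.argsort(-(raw - np.floor(raw)))[:rem]:
        counts[i] += 1
    partition = np.repeat(PARTITIONS, counts)

    assign = pd.DataFrame({"admission_id": admissions, "partition": partition})
    assign["fold"] = -1

    train_ids = assign.loc[assign["partition"] == "train", "admission_id"]
    # stratify folds on "admission ever exits to floor"
    strat = (
        table.assign(
            floor_exit=(table["label_exit_next_day"] == 1)
            & (table["label_exit_destination"] == "floor")
        )
        .groupby("admission_id")["floor_exit"]
        .any()
        .reindex(train_ids)
        .astype(int)
        .to_numpy()
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**32))
    folds = np.empty(len(train_ids), dtype=int)
    for k, (_, val_idx) in enumerate(skf.split(np.zeros(len(train_ids)), strat)):
        folds[val_idx] = k
    assign.loc[assign["partition"] == "train", "fold"] = folds
    return assign.reset_index(drop=True)


def cv_fold_indices(table: pd.DataFrame, assignment: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """Row-level (train_idx, val_idx) pairs for the training-partition folds.

    ``table`` must already be restricted to the training partition; indices
    are positional into it.
    """
    fold_of = assignment.set_index("admission_id")["fold"]
    row_fold = table["admission_id"].map(fold_of).to_numpy()
    if np.any(row_fold < 0):
        raise ValueError("table contains rows outside the training partition")
    folds = []
    for k in np.unique(row_fold):
        val = np.flatnonzero(row_fold == k)
        tr = np.flatnonzero(row_fold != k)
        folds.append((tr, val))
    return folds
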
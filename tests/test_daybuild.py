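"""Temporal labeling, forward filling, imputation and grouped splits."""

import numpy as np
import pandas as pd
import pytest

from icudca import daybuild
from icudca.cohort import CohortSpec, generate_cohort
from icudca.errors import MalformedAdmissionError


def _table(rows):
    """rows: list of dicts with admission_id, day_index, x, label."""
    df = pd.DataFrame(rows)
    if "label_exit_destination" not in df:
        df["label_exit_destination"] = np.where(
            df["label_exit_next_day"] == 1, "floor", "none"
        )
    return df


class TestAlignLabels:
    def test_three_day_exit_stay_labels(self):
        t = _table(
            [
                {"admission_id": "a", "day_index": d, "x": 1.0, "label_exit_next_day": int(d == 3)}
                for d in (1, 2, 3)
            ]
        )
        out = daybuild.align_labels(t)
        assert list(out["label_exit_next_day"]) == [0, 0, 1]

    def test_non_consecutive_days_rejected(self):
        t = _table(
            [
                {"admission_id": "a", "day_index": 1, "x": 1.0, "label_exit_next_day": 0},
                {"admission_id": "a", "day_index": 3, "x": 1.0, "label_exit_next_day": 1},
            ]
        )
        with pytest.raises(MalformedAdmissionError):
            daybuild.align_labels(t)

    def test_exit_before_last_day_rejected(self):
        t = _table(
            [
                {"admission_id": "a", "day_index": 1, "x": 1.0, "label_exit_next_day": 1},
                {"admission_id": "a", "day_index": 2, "x": 1.0, "label_exit_next_day": 0},
            ]
        )
        with pytest.raises(MalformedAdmissionError):
            daybuild.align_labels(t)

    def test_undefined_outcome_rows_dropped(self):
        t = _table(
            [
                {"admission_id": "a", "day_index": 1, "x": 1.0, "label_exit_next_day": 0.0},
                {"admission_id": "a", "day_index": 2, "x": 1.0, "label_exit_next_day": np.nan},
            ]
        )
        t["label_exit_destination"] = "none"
        out = daybuild.align_labels(t)
        assert len(out) == 1 and out["label_exit_next_day"].dtype.kind == "i"

    def test_min_days_filter_removes_short_stays(self):
        t = _table(
            [
                {"admission_id": "a", "day_index": 1, "x": 1.0, "label_exit_next_day": 1},
                {"admission_id": "b", "day_index": 1, "x": 1.0, "label_exit_next_day": 0},
                {"admission_id": "b", "day_index": 2, "x": 1.0, "label_exit_next_day": 1},
            ]
        )
        out = daybuild.align_labels(t, min_days=2)
        assert set(out["admission_id"]) == {"b"}


class TestForwardFill:
    def test_carry_forward_within_admission(self):
        t = _table(
            [
                {"admission_id": "a", "day_index": 1, "x": 5.0, "label_exit_next_day": 0},
                {"admission_id": "a", "day_index": 2, "x": np.nan, "label_exit_next_day": 0},
                {"admission_id": "a", "day_index": 3, "x": np.nan, "label_exit_next_day": 1},
            ]
        )
        assert list(daybuild.forward_fill(t)["x"]) == [5.0, 5.0, 5.0]

    def test_no_backward_fill(self):
        t = _table(
            [
                {"admission_id": "a", "day_index": 1, "x": np.nan, "label_exit_next_day": 0},
                {"admission_id": "a", "day_index": 2, "x": 3.0, "label_exit_next_day": 1},
            ]
        )
        out = daybuild.forward_fill(t)
        assert np.isnan(out["x"].iloc[0]) and out["x"].iloc[1] == 3.0

    def test_never_crosses_admissions(self):
        t = _table(
            [
                {"admission_id": "a", "day_index": 1, "x": 9.0, "label_exit_next_day": 1},
                {"admission_id": "b", "day_index": 1, "x": np.nan, "label_exit_next_day": 1},
            ]
        )
        assert np.isnan(daybuild.forward_fill(t)["x"].iloc[1])


class TestImputer:
    def test_median_and_drop_rule(self):
        n = 100
        sparse = np.full(n, np.nan)
        sparse[:39] = 1.0  # 61% missing -> above the 60% cutoff
        t = pd.DataFrame(
            {
                "admission_id": [f"a{i}" for i in range(n)],
                "day_index": 1,
                "sparse": sparse,
                "tri": np.tile([1.0, 2.0, 100.0], 34)[:n],
                "label_exit_next_day": [0, 1] * 50,
                "label_exit_destination": ["none", "floor"] * 50,
            }
        )
        model = daybuild.fit_imputer(t)
        assert "sparse" in model.dropped
        assert model.medians["tri"] == 2.0

    def test_apply_uses_training_statistics_only(self):
        train = pd.DataFrame(
            {
                "admission_id": ["a", "b", "c"],
                "day_index": 1,
                "x": [5.0, 7.5, 10.0],
                "label_exit_next_day": [0, 1, 0],
                "label_exit_destination": ["none", "floor", "none"],
            }
        )
        test = train.copy()
        test["x"] = np.nan
        model = daybuild.fit_imputer(train)
        out = daybuild.apply_imputer(model, test)
        assert (out["x"] == 7.5).all()

    def test_idempotent(self, small_cohort):
        filled = daybuild.forward_fill(small_cohort)
        model = daybuild.fit_imputer(filled)
        once = daybuild.apply_imputer(model, filled)
        twice = daybuild.apply_imputer(model, once)
        pd.testing.assert_frame_equal(once, twice)

    def test_never_observed_feature_dropped(self):
        t = pd.DataFrame(
            {
                "admission_id": ["a", "b"],
                "day_index": 1,
                "x": [np.nan, np.nan],
                "label_exit_next_day": [0, 1],
                "label_exit_destination": ["none", "floor"],
            }
        )
        model = daybuild.fit_imputer(t)
        assert model.dropped == ["x"]
        assert "x" not in daybuild.apply_imputer(model, t).columns


class TestSplits:
    def test_partition_sizes_largest_remainder(self):
        t = pd.DataFrame(
            {
                "admission_id": [f"a{i}" for i in range(1000)],
                "day_index": 1,
                "label_exit_next_day": ([0, 1] * 500),
                "label_exit_destination": (["none", "floor"] * 500),
            }
        )
        a = daybuild.split_admissions(t, seed=0)
        counts = a["partition"].value_counts()
        assert counts["train"] == 810 and counts["test"] == 90 and counts["holdout"] == 100

    def test_deterministic_and_grouped(self, small_cohort):
        a1 = daybuild.split_admissions(small_cohort, seed=5)
        a2 = daybuild.split_admissions(small_cohort, seed=5)
        pd.testing.assert_frame_equal(a1, a2)
        # every admission appears exactly once
        assert a1["admission_id"].is_unique
        assert set(a1["admission_id"]) == set(small_cohort["admission_id"])
        # all rows of an admission share a partition by construction of the map
        merged = small_cohort.merge(a1, on="admission_id")
        assert (merged.groupby("admission_id")["partition"].nunique() == 1).all()

    def test_ten_folds_inside_train_only(self, small_cohort):
        a = daybuild.split_admissions(small_cohort, seed=5, n_folds=10)
        train = a[a["partition"] == "train"]
        assert set(train["fold"]) == set(range(10))
        assert (a.loc[a["partition"] != "train", "fold"] == -1).all()

    def test_too_few_admissions_raises(self):
        t = pd.DataFrame(
            {
                "admission_id": ["a", "b"],
                "day_index": 1,
                "label_exit_next_day": [0, 1],
                "label_exit_destination": ["none", "floor"],
            }
        )
        with pytest.raises(ValueError):
            daybuild.split_admissions(t, n_folds=10)


class TestNoLeakage:
    def test_future_day_mutation_does_not_change_earlier_features(self, small_cohort):
        """Mutation oracle: perturbing raw data of later days leaves every
        feature value on earlier days unchanged through fill + imputation."""
        base = daybuild.forward_fill(small_cohort)
        model = daybuild.fit_imputer(base)
        built = daybuild.apply_imputer(model, base)

        mutated_raw = small_cohort.copy()
        adm = mutated_raw["admission_id"].iloc[0]
        sel = mutated_raw["admission_id"] == adm
        last_day = mutated_raw.loc[sel, "day_index"].max()
        if last_day == 1:  # need an admission with >1 day
            sizes = mutated_raw.groupby("admission_id")["day_index"].max()
            adm = sizes[sizes > 1].index[0]
            sel = mutated_raw["admission_id"] == adm
            last_day = sizes[adm]
        feat = "heart_rate_mean"
        mutated_raw.loc[sel & (mutated_raw["day_index"] == last_day), feat] = 999.0
        built2 = daybuild.apply_imputer(model, daybuild.forward_fill(mutated_raw))

        early = (built["admission_id"] == adm) & (built["day_index"] < last_day)
        pd.testing.assert_frame_equal(built[early], built2[early])
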
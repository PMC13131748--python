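"""Synthetic cohort generator: structure, determinism, calibration, signal."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from icudca.cohort import (
    CohortSpec,
    FeatureSpec,
    compute_mews,
    default_manifest,
    default_risk_coefficients,
    feature_columns,
    generate_cohort,
    observed_mask,
)
from icudca.errors import InfeasibleSpecError


class TestStructure:
    def test_day_index_consecutive_from_one(self, medium_cohort):
        g = medium_cohort.groupby("admission_id")
        pos = g.cumcount() + 1
        assert (medium_cohort["day_index"] == pos).all()

    def test_exit_only_on_last_day(self, medium_cohort):
        last = medium_cohort.groupby("admission_id")["day_index"].transform("max")
        early = (medium_cohort["label_exit_next_day"] == 1) & (medium_cohort["day_index"] < last)
        assert not early.any()

    def test_destination_none_iff_no_exit(self, medium_cohort):
        no_exit = medium_cohort["label_exit_next_day"] == 0
        assert (no_exit == (medium_cohort["label_exit_destination"] == "none")).all()

    def test_mask_matches_nan_pattern(self, medium_cohort):
        mask = observed_mask(medium_cohort)
        vals = medium_cohort[feature_columns(medium_cohort)]
        assert (mask == vals.notna()).all().all()


class TestDeterminismAndCalibration:
    def test_same_spec_same_table(self):
        a = generate_cohort(CohortSpec(n_admissions=500, seed=3))
        b = generate_cohort(CohortSpec(n_admissions=500, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_different_table(self):
        a = generate_cohort(CohortSpec(n_admissions=500, seed=3))
        b = generate_cohort(CohortSpec(n_admissions=500, seed=4))
        assert not a.equals(b)

    def test_prevalence_recovered_within_2pp(self, medium_cohort):
        assert len(medium_cohort) >= 10_000
        prev = medium_cohort["label_exit_next_day"].mean()
        assert abs(prev - 0.76) <= 0.02

    @pytest.mark.parametrize("target", [0.5, 0.76, 0.9])
    def test_prevalence_tracking_across_targets(self, target):
        t = generate_cohort(CohortSpec(n_admissions=4000, exit_prevalence=target, seed=5))
        assert abs(t["label_exit_next_day"].mean() - target) <= 0.03

    def test_floor_fraction_within_3pp(self, medium_cohort):
        exits = medium_cohort[medium_cohort["label_exit_next_day"] == 1]
        frac = (exits["label_exit_destination"] == "floor").mean()
        assert abs(frac - 0.77) <= 0.03

    def test_invalid_specs_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            CohortSpec(exit_prevalence=1.2).validate()
        with pytest.raises(InfeasibleSpecError):
            CohortSpec(floor_fraction=0.0).validate()
        with pytest.raises(InfeasibleSpecError):
            generate_cohort(CohortSpec(risk_coefficients={"mews": float("nan")}))
        with pytest.raises(InfeasibleSpecError):
            generate_cohort(CohortSpec(risk_coefficients={"not_a_feature": 1.0}))


class TestManifest:
    def test_reported_missingness_fractions(self):
        m = {f.name: f for f in default_manifest()}
        assert m["sbp_sd"].missingness == pytest.approx(0.458)
        assert m["fio2"].missingness == pytest.approx(0.141)
        assert m["peep"].missingness == pytest.approx(0.179)
        assert m["heart_rate_mean"].missingness < 0.01

    def test_five_domains_covered(self):
        domains = {f.domain for f in default_manifest()}
        assert domains == {"vital", "lab", "ews", "intervention", "trajectory"}

    def test_zero_missingness_gives_full_mask(self):
        manifest = tuple(
            FeatureSpec(f.name, f.domain, f.kind, f.mean, f.sd, f.rate, missingness=0.0)
            for f in default_manifest()
        )
        t = generate_cohort(CohortSpec(n_admissions=200, feature_manifest=manifest, seed=1))
        assert observed_mask(t).all().all()

    def test_injected_missingness_near_manifest_fraction(self, medium_cohort):
        assert medium_cohort["sbp_sd"].isna().mean() == pytest.approx(0.458, abs=0.02)
        assert medium_cohort["fio2"].isna().mean() == pytest.approx(0.141, abs=0.02)


class TestMews:
    def test_normal_vitals_score_zero(self):
        assert compute_mews(80, 14, 120, 37.0) == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"heart_rate": 135},
            {"resp_rate": 32},
            {"sbp": 65},
            {"temp": 39.5},
        ],
    )
    def test_single_abnormality_scores_positive(self, kwargs):
        assert compute_mews(**{"heart_rate": 80, "resp_rate": 14, "sbp": 120, "temp": 37.0, **kwargs}) > 0

    def test_all_missing_scores_zero(self):
        assert compute_mews(np.nan, np.nan, np.nan, np.nan) == 0
        assert compute_mews(None) == 0

    def test_monotone_away_from_normal_band(self):
        hr = [80, 105, 115, 135]
        scores = compute_mews(np.array(hr), 14, 120, 37.0)
        assert list(scores) == sorted(scores)
        assert scores[0] < scores[-1]


class TestSignal:
    def test_zero_coefficients_give_null_auc(self):
        coef = {k: 0.0 for k in default_risk_coefficients()}
        fit_t = generate_cohort(CohortSpec(n_admissions=3000, risk_coefficients=coef, seed=21))
        # evaluation cohort sized so the null-AUC standard error (~0.006)
        # sits well inside the +/-0.02 band
        eval_t = generate_cohort(CohortSpec(n_admissions=10000, risk_coefficients=coef, seed=22))
        feats = feature_columns(fit_t)
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
        clf.fit(fit_t[feats].fillna(0), fit_t["label_exit_next_day"])
        auc = roc_auc_score(
            eval_t["label_exit_next_day"], clf.predict_proba(eval_t[feats].fillna(0))[:, 1]
        )
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_auc_monotone_in_coefficient_scale(self):
        aucs = []
        for scale in (0.0, 0.5, 1.0):
            coef = {k: v * scale for k, v in default_risk_coefficients().items()}
            t = generate_cohort(CohortSpec(n_admissions=4000, risk_coefficients=coef, seed=9))
            if scale == 0.0:
                aucs.append(0.5)
                continue
            aucs.append(
                roc_auc_score(t["label_exit_next_day"], t["oracle_linear_predictor"])
            )
        assert aucs[0] < aucs[1] < aucs[2]
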
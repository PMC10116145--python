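"""Normative regression models, adjusted z-scores and norm refitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c3b import norms, simulate
from c3b.norms import (
    Demographics,
    ExtrapolationWarning,
    LINEAR_AGE_BASIS,
    PST_BASIS,
    SingularDesignError,
    VMT_BASIS,
    adjusted_z,
    fit_normative_model,
    nonlinear_age_term,
    predicted_score,
    select_model,
    z_from_predicted,
)


class TestNonlinearAgeTerm:
    @pytest.mark.parametrize(
        "test_id, age, expected",
        [
            ("VMT", 71.0, 0.0),
            ("VMT", 60.0, 0.0),
            ("VMT", 75.0, 16.0),
            ("PST", 50.26714, 0.0),
            ("PST", 60.26714, 100.0),
        ],
    )
    def test_basis_values(self, test_id, age, expected):
        assert nonlinear_age_term(test_id, age) == pytest.approx(expected)

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            nonlinear_age_term("MMSE", 50.0)


class TestPredictedScore:
    def test_vmt_young_patient_worked_example(self, models):
        # 30-year-old, 16 years of education, non-AA -> predicted 61.0
        demo = Demographics(age=30, education=16, sex=0, race=0)
        assert round(predicted_score(models["VMT"], demo), 1) == 61.0

    def test_pst_at_centering_point_drops_quadratic_term(self, models):
        # the quadratic age term vanishes at the centering constant; the
        # linear age term is uncentered per the published formula
        demo = Demographics(age=50.26714, education=0, sex=0, race=0)
        expected = 65.2217 - 0.4591 * 50.26714
        assert predicted_score(models["PST"], demo) == pytest.approx(expected)

    def test_vmt_prediction_continuous_and_smooth_at_knot(self, models):
        m = models["VMT"]
        f = lambda a: predicted_score(m, Demographics(age=a, education=12))
        eps = 1e-7
        assert f(71 + eps) == pytest.approx(f(71 - eps), abs=1e-5)
        # one-sided derivatives agree at the knot (the squared hinge is C1)
        h = 1e-4
        left = (f(71) - f(71 - h)) / h
        right = (f(71 + h) - f(71)) / h
        assert left == pytest.approx(right, abs=1e-2)

    def test_pst_prediction_strictly_decreasing_in_age(self, models):
        m = models["PST"]
        ages = np.linspace(18, 89, 400)
        preds = [predicted_score(m, Demographics(age=a, education=12)) for a in ages]
        assert all(b < a for a, b in zip(preds, preds[1:]))

    def test_out_of_range_age_warns_and_flags(self):
        with pytest.warns(ExtrapolationWarning):
            demo = Demographics(age=95, education=12)
        assert demo.extrapolated


class TestAdjustedZ:
    @pytest.mark.parametrize(
        "raw, predicted, rmse, expected",
        [
            (36, 59.8, 8.958, -2.66),
            (36, 31.4, 8.958, 0.51),
            (33, 61.0, 12.879, -2.17),
            (33, 42.1, 12.879, -0.71),
        ],
    )
    def test_worked_examples_from_printed_predicted_scores(self, raw, predicted, rmse, expected):
        assert round(z_from_predicted(raw, predicted, rmse), 2) == expected

    def test_raw_equal_to_predicted_gives_zero(self, models):
        demo = Demographics(age=40, education=14, sex=1, race=0)
        pred = predicted_score(models["PST"], demo)
        assert adjusted_z(pred, models["PST"], demo) == 0.0

    def test_invalid_rmse_rejected(self):
        with pytest.raises(ValueError):
            z_from_predicted(30, 40, 0.0)

    @given(
        raw=st.floats(0, 70),
        c=st.floats(-20, 20),
        rmse=st.floats(0.5, 20),
    )
    @settings(deadline=None, max_examples=50)
    def test_affine_equivariance(self, raw, c, rmse):
        # adding c to the raw score adds c/rmse to z
        base = z_from_predicted(raw, 40.0, rmse)
        shifted = z_from_predicted(raw + c, 40.0, rmse)
        assert shifted - base == pytest.approx(c / rmse, abs=1e-9)


class TestBuiltinModels:
    def test_published_coefficient_sets(self, models):
        pst, vmt = models["PST"], models["VMT"]
        assert pst.rmse == 8.958
        assert vmt.rmse == 12.879
        assert pst.beta_age == -0.4591
        assert pst.beta_sex == -2.2132
        assert vmt.beta_sex is None
        assert vmt.beta_nonlinear_age == -0.0329
        assert vmt.age_constant == 71.0
        assert pst.age_constant == 50.26714


def _noise_free_cohort(model, basis, n=400, seed=0):
    spec = simulate.SyntheticCohortSpec(
        models={model.test_id: model},
        noise_sd={model.test_id: 0.0},
        seed=seed,
        round_scores=False,
    ).scaled(n)
    return simulate.generate_normative_cohort(spec)


class TestFitNormativeModel:
    def test_noise_free_cohort_recovered_to_machine_precision(self, models):
        m = models["PST"]
        df = _noise_free_cohort(m, PST_BASIS)
        fit = fit_normative_model(df, PST_BASIS, "pst_raw", test_id="PST")
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.model.intercept == pytest.approx(m.intercept, abs=1e-8)
        assert fit.model.beta_age == pytest.approx(m.beta_age, abs=1e-10)
        assert fit.model.beta_nonlinear_age == pytest.approx(m.beta_nonlinear_age, abs=1e-10)
        assert fit.model.beta_education == pytest.approx(m.beta_education, abs=1e-9)
        assert fit.model.beta_sex == pytest.approx(m.beta_sex, abs=1e-9)
        assert fit.model.beta_race == pytest.approx(m.beta_race, abs=1e-9)

    def test_noisy_cohort_coefficients_within_3_se(self, models):
        m = models["PST"]
        spec = simulate.SyntheticCohortSpec(seed=42).scaled(5000)
        df = simulate.generate_normative_cohort(spec)
        fit = fit_normative_model(df, PST_BASIS, "pst_raw", test_id="PST")
        truth = {
            "const": m.intercept,
            "age": m.beta_age,
            "nonlinear_age": m.beta_nonlinear_age,
            "education": m.beta_education,
            "sex": m.beta_sex,
            "race": m.beta_race,
        }
        est = {
            "const": fit.model.intercept,
            "age": fit.model.beta_age,
            "nonlinear_age": fit.model.beta_nonlinear_age,
            "education": fit.model.beta_education,
            "sex": fit.model.beta_sex,
            "race": fit.model.beta_race,
        }
        for name, true_val in truth.items():
            assert abs(est[name] - true_val) < 3 * fit.standard_errors[name], name

    def test_vmt_coefficients_recovered_on_continuous_scores(self, models):
        # integer VMT scores clip at the 70-point ceiling, which flattens
        # the age slope; the round-trip property holds for the continuous
        # generating model
        m = models["VMT"]
        spec = simulate.SyntheticCohortSpec(seed=42, round_scores=False).scaled(5000)
        df = simulate.generate_normative_cohort(spec)
        fit = fit_normative_model(df, VMT_BASIS, "vmt_raw", test_id="VMT")
        truth = {
            "const": m.intercept,
            "age": m.beta_age,
            "nonlinear_age": m.beta_nonlinear_age,
            "education": m.beta_education,
            "race": m.beta_race,
        }
        est = {
            "const": fit.model.intercept,
            "age": fit.model.beta_age,
            "nonlinear_age": fit.model.beta_nonlinear_age,
            "education": fit.model.beta_education,
            "race": fit.model.beta_race,
        }
        for name, true_val in truth.items():
            assert abs(est[name] - true_val) < 3 * fit.standard_errors[name], name

    def test_rmse_recovered(self, models):
        spec = simulate.SyntheticCohortSpec(seed=42).scaled(5000)
        df = simulate.generate_normative_cohort(spec)
        fit = fit_normative_model(df, PST_BASIS, "pst_raw", test_id="PST")
        # rounding to integer scores adds 1/12 variance on top of 8.958^2
        assert fit.model.rmse == pytest.approx(8.958, rel=0.05)

    def test_constant_column_raises_singular_with_name(self, models):
        spec = simulate.SyntheticCohortSpec(seed=1).scaled(100)
        df = simulate.generate_normative_cohort(spec)
        df["education"] = 12
        with pytest.raises(SingularDesignError) as exc:
            fit_normative_model(df, PST_BASIS, "pst_raw")
        assert "education" in str(exc.value)

    def test_small_cohort_rejected(self, models):
        spec = simulate.SyntheticCohortSpec(seed=1).scaled(40)
        df = simulate.generate_normative_cohort(spec).head(10)
        with pytest.raises(ValueError):
            fit_normative_model(df, PST_BASIS, "pst_raw")


class TestSelectModel:
    def test_knot_spline_wins_on_vmt_like_data(self, models):
        spec = simulate.SyntheticCohortSpec(seed=7).scaled(5000)
        df = simulate.generate_normative_cohort(spec)
        fit = select_model(df, [LINEAR_AGE_BASIS, PST_BASIS, VMT_BASIS], "vmt_raw")
        assert fit.basis_name == "vmt_knot71_spline"

    def test_single_candidate_returned(self, models):
        spec = simulate.SyntheticCohortSpec(seed=7).scaled(200)
        df = simulate.generate_normative_cohort(spec)
        fit = select_model(df, [LINEAR_AGE_BASIS], "pst_raw")
        assert fit.basis_name == "linear_age"

    def test_pure_noise_outcome_has_near_zero_adjusted_r2(self):
        rng = np.random.default_rng(11)
        spec = simulate.SyntheticCohortSpec(seed=11).scaled(2000)
        df = simulate.generate_normative_cohort(spec)
        df["noise"] = rng.normal(size=len(df))
        fit = select_model(df, [LINEAR_AGE_BASIS, PST_BASIS, VMT_BASIS], "noise")
        assert abs(fit.adjusted_r2) < 0.02


class TestZCalibration:
    def test_mean_zero_sd_one_on_generating_cohort(self, models):
        # continuous (unclipped) scores: the integer VMT ceiling at 70
        # truncates the upper tail and would deflate the SD
        spec = simulate.SyntheticCohortSpec(seed=5, round_scores=False).scaled(4000)
        df = simulate.generate_normative_cohort(spec)
        for tid in ("PST", "VMT"):
            zs = [
                adjusted_z(
                    raw,
                    models[tid],
                    Demographics(age=a, education=e, sex=s, race=r),
                )
                for raw, a, e, s, r in zip(
                    df[f"{tid.lower()}_raw"], df["age"], df["education"], df["sex"], df["race"]
                )
            ]
            assert np.mean(zs) == pytest.approx(0.0, abs=0.06)
            assert np.std(zs, ddof=1) == pytest.approx(1.0, abs=0.06)
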
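"""Log-triglyceride regression: fitting, stepwise AIC, prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import dietsim as ds
from dietsim.regression import (
    CollinearityError,
    LogTriglycerideRegression,
    backward_stepwise_aic,
    build_design,
    covariate_means,
    fit_ols_log_tg,
    percent_change,
)
from dietsim.survey import GeneratorConfig, default_beta_true, generate_population

TRUE_TERMS = (
    "age", "bmi", "hdl_c", "fasting_glucose", "family_history_diabetes",
    "smoking_status", "country_of_birth",
    "protein", "fat", "fibre", "saturated_fat", "monounsaturated_fat",
    "linoleic_acid", "lc_omega3",
)


def toy_records(rng, n=200, p=4, beta=None, sigma=0.1):
    """Small synthetic records with generic nutrient-named predictors."""
    cols = ["protein", "fat", "fibre", "sodium", "calcium", "iron",
            "zinc", "sugars", "alcohol", "iodine"][:p]
    X = rng.normal(size=(n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    eta = 0.1 + X @ beta
    df = pd.DataFrame(X, columns=cols)
    df["triglycerides"] = np.exp(eta + sigma * rng.normal(size=n))
    return df, cols


class TestFit:
    def test_noiseless_fit_recovers_true_coefficients(self):
        beta = default_beta_true()
        df = generate_population(GeneratorConfig(n=2000, seed=11, sigma=0.0))
        model = fit_ols_log_tg(df, TRUE_TERMS)
        for term in ("protein", "fat", "fibre", "lc_omega3", "bmi", "hdl_c"):
            assert model.params[term] == pytest.approx(beta[term], rel=1e-6), term

    def test_intercept_only_predicts_geometric_mean(self, rng):
        df, _ = toy_records(rng, n=50, p=1)
        model = fit_ols_log_tg(df, terms=())
        want = np.exp(np.mean(np.log(df["triglycerides"])))
        point, _ = model.predict({})
        assert point == pytest.approx(want)

    def test_saturated_design_is_an_error(self, rng):
        df, cols = toy_records(rng, n=5, p=4)
        with pytest.raises(ValueError, match="[Ss]aturated"):
            fit_ols_log_tg(df, cols)

    def test_rank_deficient_design_names_collinear_terms(self, rng):
        df, cols = toy_records(rng, n=100, p=3)
        df["sodium"] = 2.0 * df["protein"]  # exact collinearity
        with pytest.raises(CollinearityError, match="protein|sodium"):
            fit_ols_log_tg(df, cols + ["sodium"])

    def test_nonpositive_outcome_rejected(self, rng):
        df, cols = toy_records(rng, n=50, p=2)
        df.loc[0, "triglycerides"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_ols_log_tg(df, cols)

    def test_rmse_is_original_scale(self, rng):
        df, cols = toy_records(rng, n=500, p=2, beta=[0.3, -0.2], sigma=0.05)
        model = fit_ols_log_tg(df, cols)
        assert 0 < model.rmse < 0.2  # mmol/L-scale residual spread


class TestBackwardStepwise:
    def test_all_protected_returns_full_model(self, rng):
        df, cols = toy_records(rng, n=100, p=3, beta=[0.5, 0.0, -0.5])
        full = fit_ols_log_tg(df, cols)
        kept = backward_stepwise_aic(df, cols, protected=cols)
        assert kept.terms == full.terms
        assert kept.aic == pytest.approx(full.aic)
        assert kept.aic_trail == ()

    def test_selected_aic_never_exceeds_full_model(self, rng):
        df, cols = toy_records(rng, n=300, p=6, beta=[0.5, 0, -0.4, 0, 0.3, 0])
        full = fit_ols_log_tg(df, cols)
        sel = backward_stepwise_aic(df, cols)
        assert sel.aic <= full.aic + 1e-9

    def test_trail_aic_is_strictly_decreasing(self, rng):
        df, cols = toy_records(rng, n=300, p=8, beta=[0.5, 0, 0, 0, 0.3, 0, 0, 0])
        sel = backward_stepwise_aic(df, cols)
        aics = [a for _, _, a in sel.aic_trail]
        assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_matches_exhaustive_subset_search_on_toy_data(self, rng):
        df, cols = toy_records(rng, n=200, p=3, beta=[0.4, 0.0, 0.25], sigma=0.2)
        sel = backward_stepwise_aic(df, cols)
        best = min(
            (
                fit_ols_log_tg(df, subset).aic
                for r in range(len(cols) + 1)
                for subset in itertools.combinations(cols, r)
            ),
        )
        assert sel.aic == pytest.approx(best, abs=1e-9)

    def test_null_term_drop_rate_matches_aic_theory(self):
        """A single zero-coefficient term survives backward AIC selection
        with probability P(chi2_1 >= 2) ~ 0.157, so across seeded
        replicates the drop rate should be near 84%, not near 100%."""
        rng = np.random.default_rng(606)
        dropped = 0
        reps = 100
        for _ in range(reps):
            df, cols = toy_records(
                rng, n=500, p=5, beta=[0.5, -0.4, 0.3, 0.2, 0.0], sigma=0.3
            )
            sel = backward_stepwise_aic(df, cols)
            dropped += cols[-1] not in sel.terms
        assert 72 <= dropped <= 95

    def test_unknown_protected_term_rejected(self, rng):
        df, cols = toy_records(rng, n=100, p=2)
        with pytest.raises(ValueError, match="not in model"):
            backward_stepwise_aic(df, cols, protected=["bmi"])


class TestPrediction:
    def test_intercept_only_degenerate_ci(self):
        model = ds.TGModel(
            terms=(),
            params=pd.Series({"intercept": 0.2}),
            cov=pd.DataFrame([[0.0]], index=["intercept"], columns=["intercept"]),
        )
        point, (lo, hi) = model.predict({})
        assert point == lo == hi == pytest.approx(np.exp(0.2))

    def test_delta_method_ci_is_asymmetric_around_point(self, demo_model, baseline_table):
        x = baseline_table.aggregate_total().to_dict()
        point, (lo, hi) = demo_model.predict(x)
        assert lo < point < hi
        assert (hi - point) > (point - lo)  # exp back-transform skews upward

    def test_demo_model_reproduces_published_baseline(self, demo_model, baseline_table):
        x = baseline_table.aggregate_total().to_dict()
        point, (lo, hi) = demo_model.predict(x)
        assert round(point, 3) == 0.935
        assert round(lo, 3) == 0.893
        assert round(hi, 3) == 0.979

    def test_missing_term_in_x_is_error(self, demo_model):
        with pytest.raises(KeyError, match="protein"):
            demo_model.predict({"fat": 1.0})

    def test_scenario_change_matches_closed_form(self, baseline_table, demo_model):
        """Propagated percent change equals 100*(exp(dx . beta) - 1)."""
        lib = ds.scenario_library()
        spec = next(s for s in lib if s.id == "S3a.m2")
        res = ds.evaluate_scenarios(demo_model, baseline_table, [spec])[0]
        dx = (
            ds.run_scenario(baseline_table, spec).aggregate_total().series
            - baseline_table.aggregate_total().series
        )
        want = 100 * (np.exp(sum(
            demo_model.params[t] * dx[t] for t in demo_model.terms
        )) - 1)
        assert res.percent_change == pytest.approx(want, abs=1e-9)

    def test_coefficient_csv_roundtrip(self, tmp_path, demo_model, baseline_table):
        p = tmp_path / "coef.csv"
        pd.DataFrame({
            "term": demo_model.params.index,
            "beta": demo_model.params.values,
            "se": np.sqrt(np.diag(demo_model.cov)),
        }).to_csv(p, index=False)
        again = ds.TGModel.from_coefficients_csv(p)
        x = baseline_table.aggregate_total().to_dict()
        a_point, (a_lo, a_hi) = again.predict(x)
        d_point, (d_lo, d_hi) = demo_model.predict(x)
        assert (a_point, a_lo, a_hi) == pytest.approx((d_point, d_lo, d_hi))


class TestPercentChange:
    @pytest.mark.parametrize(
        "baseline,modelled,expected",
        [(0.935, 0.924, -1.2), (0.935, 0.909, -2.8), (1.0, 1.0, 0.0)],
    )
    def test_reported_percent_changes(self, baseline, modelled, expected):
        assert percent_change(baseline, modelled) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestSklearnEstimator:
    def test_fit_predict_and_fitted_attributes(self, small_survey):
        est = LogTriglycerideRegression(terms=TRUE_TERMS, stepwise=False)
        est.fit(small_survey.drop(columns=["triglycerides"]),
                small_survey["triglycerides"])
        assert est.n_ == len(small_survey)
        preds = est.predict(small_survey)
        assert preds.shape == (len(small_survey),)
        assert (preds > 0).all()

    def test_clone_and_get_params_roundtrip(self):
        est = LogTriglycerideRegression(terms=("protein",), stepwise=True,
                                        protected=("protein",))
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_stepwise_estimator_records_trail(self, small_survey):
        est = LogTriglycerideRegression(terms=TRUE_TERMS, stepwise=True)
        est.fit(small_survey)
        assert est.model_.terms  # something survives
        for step, term, _ in est.aic_trail_:
            assert term not in est.model_.terms

    def test_population_prediction_interface(self, small_survey, baseline_table):
        est = LogTriglycerideRegression(terms=("protein", "fibre"), stepwise=False)
        est.fit(small_survey)
        x = baseline_table.aggregate_total().to_dict()
        point, (lo, hi) = est.predict_population(x)
        assert lo <= point <= hi


def test_covariate_means_uses_dummy_proportions(small_survey):
    means = covariate_means(small_survey, ("smoking_status", "bmi"))
    assert 0 < means["smoking_status_ex"] < 1
    assert means["bmi"] == pytest.approx(small_survey["bmi"].mean())


def test_design_expands_categoricals(small_survey):
    X, groups = build_design(small_survey, ["smoking_status", "age"])
    assert groups["smoking_status"] == ["smoking_status_ex", "smoking_status_current"]
    assert set(X.columns) == {
        "intercept", "smoking_status_ex", "smoking_status_current", "age"
    }
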
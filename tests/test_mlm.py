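"""Three-level mixed models: design, likelihood oracle, fitting, inference."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from nutripanel.mlm import (
    FitResult,
    ModelSpec,
    VarianceComponents,
    build_design,
    dense_loglik,
    fit,
    icc,
    icc_from_components,
    information_criteria,
    likelihood_ratio_test,
    pseudo_r2,
    run_model_sequence,
)
from nutripanel.synth import TrueParams, simulate_panel

GROWTH_SPEC = ModelSpec(
    fixed=("intercept", "year_centered"),
    county_random=("intercept", "year"),
    state_random=("intercept", "year"),
)


class TestModelSpec:
    def test_random_slope_requires_fixed_year(self):
        with pytest.raises(ValueError, match="year_centered"):
            ModelSpec(fixed=("intercept",), county_random=("intercept", "year"))

    def test_random_slope_requires_random_intercept(self):
        with pytest.raises(ValueError, match="random intercept"):
            ModelSpec(fixed=("intercept", "year_centered"), county_random=("year",))

    def test_intercept_mandatory(self):
        with pytest.raises(ValueError, match="intercept"):
            ModelSpec(fixed=("year_centered",))

    @pytest.mark.parametrize(
        "spec,k",
        [
            (ModelSpec(), 4),  # intercept + 2 intercept vars + residual
            (GROWTH_SPEC, 9),  # 2 fixed + 2x(2 vars + cov) + residual
            (replace(GROWTH_SPEC, fixed=("intercept", "year_centered",
                                         "fsa_score_of_means")), 10),
            (replace(GROWTH_SPEC, fixed=("intercept", "year_centered",
                                         "mean_fat", "mean_sugar")), 11),
        ],
    )
    def test_parameter_counting_rule(self, spec, k):
        assert spec.k() == k


class TestBuildDesign:
    def test_year_centered_at_origin(self, hand_panel):
        design = build_design(hand_panel.drop(columns="year_centered"), ModelSpec())
        years = sorted(set(hand_panel["year"]))
        assert years == [2004, 2005, 2006]
        t = []
        for st in design.states:
            t.extend(np.unique(st.Z_state[:, 0]))  # intercept column, all ones
        assert set(t) == {1.0}

    def test_intercept_only_design_is_all_ones(self, hand_panel):
        design = build_design(hand_panel, ModelSpec())
        assert design.X.shape[1] == 1
        assert (design.X == 1.0).all()

    def test_group_counts(self, hand_panel):
        design = build_design(hand_panel, GROWTH_SPEC)
        assert design.n == 12
        assert design.n_counties == 4
        assert design.n_states == 2

    def test_county_in_two_states_rejected(self, hand_panel):
        bad = hand_panel.copy()
        bad.loc[bad.index[-1], "county_id"] = 1001  # county 1001 now in both states
        with pytest.raises(ValueError, match="more than one state"):
            build_design(bad, ModelSpec())

    def test_empty_design_rejected(self, hand_panel):
        empty = hand_panel.assign(obesity=np.nan)
        with pytest.raises(ValueError, match="empty design"):
            build_design(empty, ModelSpec())

    def test_constant_covariate_rejected(self, hand_panel):
        flat = hand_panel.assign(mean_fat=5.0)
        with pytest.raises(ValueError, match="constant"):
            build_design(flat, replace(GROWTH_SPEC,
                                       fixed=("intercept", "year_centered", "mean_fat")))


class TestDenseLoglik:
    def test_single_observation_standard_normal(self):
        panel = pd.DataFrame(
            {"state_id": [1], "county_id": [1001], "year": [2004], "obesity": [0.0]}
        )
        spec = ModelSpec(fixed=("intercept",), county_random=(), state_random=())
        design = build_design(panel, spec)
        ll = dense_loglik([0.0], VarianceComponents(residual_var=1.0), design, method="ML")
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_block_additivity_across_states(self, hand_panel):
        spec = ModelSpec()
        vc = VarianceComponents(county_intercept_var=2.0, state_intercept_var=1.0,
                                residual_var=0.5)
        full = build_design(hand_panel, spec)
        ll_full = dense_loglik([25.0], vc, full, method="ML")
        parts = 0.0
        for sid in (1, 2):
            sub = build_design(hand_panel[hand_panel.state_id == sid], spec)
            parts += dense_loglik([25.0], vc, sub, method="ML")
        assert ll_full == pytest.approx(parts, abs=1e-10)

    @pytest.mark.parametrize("method", ["ML", "REML"])
    def test_oracle_agrees_with_fitter_objective(self, method, intercepts_params):
        """Fitted objective equals the dense-covariance log-density, ~60-row fixture."""
        panel, _ = simulate_panel(intercepts_params, n_states=4, counties_per_state=3,
                                  years=range(2004, 2009), seed=17)
        spec = ModelSpec(method=method)
        result = fit(spec, panel)
        beta = [result.fixed_effects[n] for n in result.design.fixed_names]
        oracle = dense_loglik(beta, result.components, result.design, method=method)
        assert abs(oracle - result.loglik) < 1e-6


class TestFit:
    def test_parameter_recovery_single_large_panel(self):
        params = TrueParams()
        panel, _ = simulate_panel(params, n_states=50, counties_per_state=6, seed=1)
        spec = ModelSpec(
            fixed=("intercept", "year_centered", "mean_fat", "mean_sugar"),
            county_random=("intercept", "year"),
            state_random=("intercept", "year"),
        )
        result = fit(spec, panel)
        assert result.converged
        truth = {
            "intercept": params.intercept,
            "year_centered": params.year_slope,
            "mean_fat": 0.19,
            "mean_sugar": 0.08,
        }
        for name, true_val in truth.items():
            err = abs(result.fixed_effects[name] - true_val)
            assert err < 3 * result.fixed_se[name], name
        c = result.components
        assert abs(c.county_intercept_var - 9.0) / 9.0 < 0.3
        assert abs(c.residual_var - 1.0) < 0.3

    def test_zero_slope_variance_recovered_at_boundary(self):
        params = TrueParams(
            nutrition_coefficients={}, county_slope_var=0.0, county_cov=0.0,
            state_slope_var=0.0, state_cov=0.0,
        )
        panel, _ = simulate_panel(params, n_states=20, counties_per_state=4, seed=3)
        result = fit(GROWTH_SPEC, panel)
        assert result.components.county_slope_var < 0.02
        assert result.components.state_slope_var < 0.02

    def test_ml_loglik_never_decreases_with_added_fixed_term(self, intercepts_params):
        panel, _ = simulate_panel(
            replace(intercepts_params, nutrition_coefficients={"mean_fat": 0.0}),
            n_states=8, counties_per_state=4, years=range(2004, 2009), seed=5,
        )
        base = fit(ModelSpec(fixed=("intercept", "year_centered"), method="ML"), panel)
        bigger = fit(
            ModelSpec(fixed=("intercept", "year_centered", "mean_fat"), method="ML"), panel
        )
        assert bigger.loglik >= base.loglik - 1e-6

    def test_ols_limit_with_null_spec(self, hand_panel):
        """With no random effects the fixed effects equal ordinary least squares."""
        spec = ModelSpec(fixed=("intercept", "year_centered", "mean_fat"),
                         county_random=(), state_random=(), method="ML")
        result = fit(spec, hand_panel)
        X = np.column_stack(
            [np.ones(len(hand_panel)), hand_panel["year_centered"], hand_panel["mean_fat"]]
        )
        beta_ols, *_ = np.linalg.lstsq(X, hand_panel["obesity"].to_numpy(), rcond=None)
        fitted = [result.fixed_effects[n] for n in ("intercept", "year_centered", "mean_fat")]
        assert np.allclose(fitted, beta_ols, atol=1e-8)

    def test_too_few_groups_rejected(self, hand_panel):
        single_state = hand_panel[hand_panel.state_id == 1]
        with pytest.raises(ValueError, match=">= 2 states"):
            fit(ModelSpec(), single_state)

    def test_statsmodels_cross_check_nested_intercepts(self, intercepts_params):
        """Independent reference: statsmodels MixedLM with a nested variance component."""
        sm = pytest.importorskip("statsmodels.api")
        panel, _ = simulate_panel(intercepts_params, n_states=10, counties_per_state=4,
                                  years=range(2004, 2010), seed=11)
        ours = fit(ModelSpec(method="ML"), panel)

        df = panel.copy()
        model = sm.MixedLM.from_formula(
            "obesity ~ 1",
            groups="state_id",
            re_formula="1",
            vc_formula={"county": "0 + C(county_id)"},
            data=df,
        )
        ref = model.fit(reml=False, method="lbfgs", maxiter=500)
        assert ours.fixed_effects["intercept"] == pytest.approx(
            ref.fe_params.iloc[0], abs=1e-3
        )
        assert ours.components.state_intercept_var == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=2e-2, abs=1e-3
        )
        assert ours.components.county_intercept_var == pytest.approx(
            float(ref.vcomp[0]), rel=2e-2, abs=1e-3
        )
        assert ours.components.residual_var == pytest.approx(ref.scale, rel=2e-2)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-3)


class TestInformationCriteria:
    def test_aic_from_printed_loglik(self):
        result = FitResult(loglik=-3394.31, k=4, n=1675)
        aic, _ = information_criteria(result)
        assert aic == pytest.approx(6796.62, abs=0.02)

    def test_bic_from_printed_loglik(self):
        aic, bic = information_criteria(FitResult(loglik=-3089.36, k=11, n=1675))
        assert bic == pytest.approx(6260.38, abs=0.02)

    def test_zero_loglik_zero_params(self):
        assert information_criteria(FitResult(loglik=0.0, k=0, n=10)) == (0.0, 0.0)


class TestLikelihoodRatioTest:
    def test_identical_fits_statistic_zero_p_one(self, intercepts_params):
        panel, _ = simulate_panel(intercepts_params, n_states=5, counties_per_state=3,
                                  years=range(2004, 2008), seed=2)
        a = fit(ModelSpec(method="ML"), panel)
        statistic, df, p = likelihood_ratio_test(a, a)
        assert statistic == pytest.approx(0.0, abs=1e-6)
        assert df == 0
        assert p == 1.0

    def test_growth_vs_fsa_pair_has_df_one(self, intercepts_params):
        panel, _ = simulate_panel(intercepts_params, n_states=6, counties_per_state=4,
                                  years=range(2004, 2010), seed=4)
        rng = np.random.default_rng(0)
        panel["fsa_score_of_means"] = rng.normal(8, 1, len(panel))
        base = fit(GROWTH_SPEC, panel)
        full = fit(replace(GROWTH_SPEC,
                           fixed=("intercept", "year_centered", "fsa_score_of_means")), panel)
        statistic, df, p = likelihood_ratio_test(base, full)
        assert df == 1
        assert 0 <= p <= 1

    def test_non_nested_pair_rejected(self, intercepts_params):
        panel, _ = simulate_panel(intercepts_params, n_states=5, counties_per_state=3,
                                  years=range(2004, 2008), seed=6)
        rng = np.random.default_rng(1)
        panel["mean_fat"] = rng.normal(10, 2, len(panel))
        panel["fsa_score_of_means"] = rng.normal(8, 1, len(panel))
        a = fit(ModelSpec(fixed=("intercept", "mean_fat"), method="ML"), panel)
        b = fit(ModelSpec(fixed=("intercept", "fsa_score_of_means"), method="ML"), panel)
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(a, b)

    def test_reml_fits_are_refit_with_ml_for_fixed_effect_tests(self, intercepts_params):
        panel, _ = simulate_panel(intercepts_params, n_states=6, counties_per_state=4,
                                  years=range(2004, 2010), seed=8)
        rng = np.random.default_rng(2)
        panel["mean_fat"] = rng.normal(10, 2, len(panel))
        base = fit(ModelSpec(method="REML"), panel)
        full = fit(ModelSpec(fixed=("intercept", "mean_fat"), method="REML"), panel)
        statistic, df, p = likelihood_ratio_test(base, full)
        # the ML statistic must match a direct ML fit of both models
        base_ml = fit(ModelSpec(method="ML"), panel)
        full_ml = fit(ModelSpec(fixed=("intercept", "mean_fat"), method="ML"), panel)
        assert statistic == pytest.approx(2 * (full_ml.loglik - base_ml.loglik), abs=1e-4)


class TestIccAndPseudoR2:
    def test_icc_from_variance_components(self):
        out = icc_from_components(8.90, 4.87, 1.79)
        assert round(out["county:state"], 2) == 0.88
        assert round(out["state"], 2) == 0.31

    def test_icc_zero_residual_is_one(self):
        out = icc_from_components(2.0, 1.0, 0.0)
        assert out["county:state"] == pytest.approx(1.0)

    def test_icc_no_random_variance_is_zero(self):
        out = icc_from_components(0.0, 0.0, 1.5)
        assert out["county:state"] == 0.0
        assert out["state"] == 0.0

    def test_icc_requires_intercept_only_model(self):
        result = FitResult(spec=GROWTH_SPEC,
                           components=VarianceComponents(residual_var=1.0))
        with pytest.raises(ValueError, match="intercept-only"):
            icc(result)

    def test_icc_bounds_on_fitted_model(self, intercepts_params):
        panel, _ = simulate_panel(intercepts_params, n_states=8, counties_per_state=4,
                                  years=range(2004, 2009), seed=13)
        result = fit(ModelSpec(), panel)
        out = icc(result)
        assert 0 <= out["state"] <= out["county:state"] <= 1

    def test_pseudo_r2_printed_residuals(self):
        base = FitResult(components=VarianceComponents(residual_var=1.79))
        ext = FitResult(components=VarianceComponents(residual_var=0.97))
        assert pseudo_r2(base, ext) == pytest.approx((1.79 - 0.97) / 1.79)

    def test_pseudo_r2_edge_cases(self):
        same = FitResult(components=VarianceComponents(residual_var=1.0))
        assert pseudo_r2(same, same) == 0.0
        tiny = FitResult(components=VarianceComponents(residual_var=1e-300))
        assert pseudo_r2(same, tiny) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def sequence_panel():
    params = TrueParams()  # nonzero fat and sugar effects
    panel, _ = simulate_panel(params, n_states=15, counties_per_state=4, seed=19)
    rng = np.random.default_rng(19)
    # FSA-like coarse composite: correlated with fat+sugar but noisier
    raw = 4 + (panel["mean_fat"] + panel["mean_sugar"]) / 4 + rng.normal(0, 1, len(panel))
    panel["fsa_score_of_means"] = np.clip(np.round(raw), 4, 12)
    return panel


@pytest.fixture(scope="module")
def comparison(sequence_panel):
    return run_model_sequence(sequence_panel)


class TestModelSequence:
    def test_model_1_has_no_year_terms(self, comparison):
        m1 = comparison.fit_by_label("Model 1")
        assert "year_centered" not in m1.spec.fixed
        assert "year" not in m1.spec.county_random
        assert "year" not in m1.spec.state_random

    def test_model_4_attains_lowest_aic(self, comparison):
        crit = comparison.criteria.set_index("label")["AIC"]
        models = ["Model 1", "Model 2", "Model 3", "Model 4"]
        assert crit["Model 4"] == min(crit[m] for m in models)

    def test_lrt_degrees_of_freedom_follow_specs(self, comparison):
        by_pair = {(r["nested"], r["full"]): r["df"] for r in comparison.lrt_rows}
        assert by_pair[("Null", "Model 1")] == 2
        assert by_pair[("Model 1", "Model 2")] == 5
        assert by_pair[("Model 2", "Model 3")] == 1
        assert by_pair[("Model 2", "Model 4")] == 2

    def test_all_fits_share_data(self, comparison):
        assert len({f.n for f in comparison.fits}) == 1
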
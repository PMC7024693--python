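"""Multinomial fitter, staged comparison, LR tests and inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from sdqchange import (
    CohortConfig,
    classify_cohort,
    fit_multinomial,
    generate,
    likelihood_ratio_test,
    null_fit_from_counts,
    significance_policy,
    staged_comparison,
)
from sdqchange.multinomial import (
    ModelError,
    ModelSpec,
    OUTCOME_LEVELS,
    _log_likelihood,
    _probabilities,
    build_design,
    fit_multinomial_arrays,
    standardize_continuous,
)

PRINTED_ABOVE = {"improvement": 620, "deterioration": 198, "no_change": 1452}
PRINTED_BELOW = {"improvement": 290, "deterioration": 813, "no_change": 5701}


@pytest.fixture(scope="module")
def fitted200():
    cfg = CohortConfig(n=200, seed=42, effect_log_odds={"gender_female": (0.6, -0.2)})
    records = generate(cfg)
    results = classify_cohort(records)
    spec = ModelSpec(predictors=("t1_emotional", "gender_female"))
    return records, results, spec, fit_multinomial(spec, records, results)


class TestStandardization:
    def test_columns_become_mean_zero_unit_sd(self, classified300):
        records, results = classified300
        X, _, moments = build_design(records, results, ModelSpec.for_stage("full"))
        for term in ("t1_emotional", "attainment", "quality_of_life"):
            assert abs(X[term].mean()) < 1e-12
            assert X[term].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
            assert term in moments

    def test_location_invariance(self):
        base = pd.DataFrame({"attainment": [20.0, 25.0, 30.0, 35.0]})
        shifted = base + 100.0
        a, _ = standardize_continuous(base)
        b, _ = standardize_continuous(shifted)
        assert np.allclose(a["attainment"], b["attainment"])

    def test_zero_variance_predictor_named(self):
        frame = pd.DataFrame({"attainment": [5.0, 5.0, 5.0]})
        with pytest.raises(ModelError, match="attainment"):
            standardize_continuous(frame)

    def test_scale_invariance_of_coefficients(self, classified300):
        """Multiplying a continuous predictor by a constant before
        standardization cannot change the fitted coefficients."""
        records, results = classified300
        spec = ModelSpec(predictors=("t1_emotional", "attainment"))
        fit = fit_multinomial(spec, records, results)
        X, y, _ = build_design(records, results, spec, standardize=False)
        X["attainment"] *= 10.0
        X[["t1_emotional", "attainment"]], _ = standardize_continuous(
            X[["t1_emotional", "attainment"]]
        )
        refit = fit_multinomial_arrays(X.to_numpy(), y, tuple(X.columns))
        assert np.allclose(fit.coefficients, refit.coefficients, atol=1e-7)


class TestInterceptOnly:
    def test_fitted_probabilities_are_sample_proportions(self):
        fit = null_fit_from_counts(PRINTED_ABOVE)
        probs = _probabilities(np.ones((1, 1)), fit.coefficients)[0]
        assert probs[0] == pytest.approx(1452 / 2270, abs=1e-10)
        assert probs[1] == pytest.approx(620 / 2270, abs=1e-10)
        assert probs[2] == pytest.approx(198 / 2270, abs=1e-10)

    def test_closed_form_agrees_with_newton_on_expanded_outcome(self):
        """Dual route: the count-based closed form and the iterative
        fitter on the expanded outcome give the same LL and AIC."""
        fit = null_fit_from_counts(PRINTED_ABOVE)
        y = np.repeat([1, 2, 0], [620, 198, 1452])
        newton = fit_multinomial_arrays(np.ones((y.size, 1)), y, ("intercept",))
        assert newton.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-8)
        assert newton.aic == pytest.approx(fit.aic, abs=1e-6)
        assert np.allclose(newton.coefficients, fit.coefficients, atol=1e-7)

    def test_two_free_parameter_aic_convention(self):
        fit = null_fit_from_counts(PRINTED_ABOVE)
        assert fit.n_params == 2
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 4)

    def test_empty_category_rejected(self):
        with pytest.raises(ModelError, match="no observations"):
            null_fit_from_counts({"improvement": 5, "deterioration": 0, "no_change": 5})


class TestFitting:
    def test_gradient_vanishes_at_reported_optimum(self, fitted200):
        records, results, spec, fit = fitted200
        X, y, _ = build_design(records, results, spec)
        probs = _probabilities(X.to_numpy(), fit.coefficients)[:, 1:]
        ind = np.column_stack([y == 1, y == 2]).astype(float)
        grad = np.concatenate(
            [X.to_numpy().T @ (ind[:, j] - probs[:, j]) for j in range(2)]
        )
        assert np.max(np.abs(grad)) < 1e-6

    def test_agrees_with_derivative_free_optimizer(self, fitted200):
        """Nelder-Mead from a cold start reaches the same maximum LL to
        four decimals on a 200-record fixture."""
        records, results, spec, fit = fitted200
        X, y, _ = build_design(records, results, spec)
        Xm = X.to_numpy()

        def negll(theta):
            return -_log_likelihood(Xm, y, theta.reshape(2, -1))

        sol = optimize.minimize(
            negll,
            np.zeros(fit.coefficients.size),
            method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10},
        )
        assert -sol.fun == pytest.approx(fit.log_likelihood, abs=1e-4)

    def test_agrees_with_statsmodels_mnlogit(self, fitted200):
        sm = pytest.importorskip("statsmodels.api")
        records, results, spec, fit = fitted200
        X, y, _ = build_design(records, results, spec)
        ref = sm.MNLogit(y, X.to_numpy()).fit(disp=0)
        assert ref.llf == pytest.approx(fit.log_likelihood, abs=1e-6)
        assert np.allclose(fit.coefficients, ref.params.T, atol=1e-6)

    def test_single_category_outcome_rejected(self):
        y = np.zeros(50, dtype=int)
        with pytest.raises(ModelError, match="single observed category"):
            fit_multinomial_arrays(np.ones((50, 1)), y, ("intercept",))

    def test_rank_deficient_design_names_collinear_terms(self, classified300):
        records, results = classified300
        X, y, _ = build_design(records, results, ModelSpec(predictors=("fsm",)))
        X["fsm_copy"] = X["fsm"]
        with pytest.raises(ModelError, match="rank deficient"):
            fit_multinomial_arrays(X.to_numpy(), y, tuple(X.columns))

    def test_separation_diagnosed(self):
        x = np.repeat([0.0, 1.0], 40)
        y = np.repeat([0, 1], 40)
        X = np.column_stack([np.ones(80), x])
        with pytest.raises(ModelError, match="separation"):
            fit_multinomial_arrays(X, y, ("intercept", "x"))

    def test_wald_summary_invariants(self, fitted200):
        *_, fit = fitted200
        frame = fit.summary_frame()
        assert np.allclose(frame["odds_ratio"], np.exp(frame["coef"]))
        assert np.allclose(frame["ci_low"], np.exp(frame["coef"] - 1.96 * frame["se"]))
        assert np.allclose(frame["ci_high"], np.exp(frame["coef"] + 1.96 * frame["se"]))
        assert 0.0 <= fit.mcfadden_r2 < 1.0


class TestLikelihoodRatioAndStages:
    def test_identical_models_give_zero_lr(self, fitted200):
        *_, fit = fitted200
        res = likelihood_ratio_test(fit, fit)
        assert res.lr_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_non_nested_specs_rejected(self, classified300):
        records, results = classified300
        a = fit_multinomial(ModelSpec(predictors=("fsm",)), records, results)
        b = fit_multinomial(ModelSpec(predictors=("sen",)), records, results)
        with pytest.raises(ModelError, match="not nested"):
            likelihood_ratio_test(a, b)

    def test_reconstructed_lr_from_published_aics(self):
        """LL_null from the above-threshold counts plus the published full
        AIC (3686, 40 free parameters) reconstructs LR = 266.9."""
        null = null_fit_from_counts(PRINTED_ABOVE)
        ll_full = -(3686 - 2 * 40) / 2.0
        lr = 2.0 * (ll_full - null.log_likelihood)
        assert lr == pytest.approx(266.93, abs=1.5)

    def test_staged_sequence_monotone_and_consistent(self, classified300):
        records, results = classified300
        table = staged_comparison(records, results, "full")
        assert list(table["stage"]) == [
            "null",
            "severity",
            "severity+demographics",
            "severity+demographics+context",
            "full",
        ]
        ll = table["log_likelihood"].to_numpy()
        assert np.all(np.diff(ll) >= -1e-9)  # adding terms never hurts LL
        counts = {
            c: sum(r.overall == c for r in results)
            for c in ("improvement", "deterioration", "no_change")
        }
        assert table.loc[table.stage == "null", "aic"].iloc[0] == pytest.approx(
            null_fit_from_counts(counts).aic, abs=1e-6
        )
        assert table.loc[table.stage == "full", "n_params"].iloc[0] == 40

    def test_stage_term_sets_are_nested(self):
        from sdqchange.multinomial import STAGES

        stages = list(STAGES.values())
        for smaller, larger in zip(stages, stages[1:]):
            assert set(smaller) <= set(larger)


class TestSignificancePolicy:
    @pytest.mark.parametrize(
        "label,alpha", [("full", 0.05), ("above", 0.025), ("below", 0.025)]
    )
    def test_alpha_per_sample(self, label, alpha):
        assert significance_policy(label) == alpha

    def test_unknown_label_rejected(self):
        with pytest.raises(ModelError):
            significance_policy("everyone")
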
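import math

import numpy as np
import pandas as pd
import pytest

from declina.inference import (
    FittedModel,
    InferenceError,
    TwoByTwo,
    build_design,
    fit_logistic,
    fit_model,
    nagelkerke_r2,
    odds_ratio,
    predicted_risk,
)


class TestOddsRatio:
    def test_polypharmacy_table(self):
        """2x2 from a published univariate table: OR 1.33, CI 1.05-1.70."""
        or_, lo, hi = odds_ratio(TwoByTwo(a=287, b=107, c=1214, d=603))
        assert round(or_, 2) == 1.33
        assert round(lo, 2) == 1.05
        assert round(hi, 2) == 1.70

    def test_symmetry_and_cross_product(self):
        assert odds_ratio(TwoByTwo(10, 10, 10, 10))[0] == pytest.approx(1.0)
        assert odds_ratio(TwoByTwo(2, 1, 1, 2))[0] == pytest.approx(4.0)

    def test_zero_cell(self):
        with pytest.raises(InferenceError, match="continuity"):
            odds_ratio(TwoByTwo(0, 5, 5, 5))
        or_, lo, hi = odds_ratio(TwoByTwo(0, 5, 5, 5), continuity=True)
        assert 0 < lo < or_ < hi


def _binary_frame(t: TwoByTwo) -> pd.DataFrame:
    """Expand 2x2 counts into unit records."""
    rows = (
        [{"x": 1, "y": 1}] * t.a + [{"x": 0, "y": 1}] * t.b
        + [{"x": 1, "y": 0}] * t.c + [{"x": 0, "y": 0}] * t.d
    )
    return pd.DataFrame(rows)


class TestFitLogistic:
    def test_slope_equals_log_odds_ratio(self, rng):
        """Saturated 2x2 model: the ML slope is exactly ln((a d)/(b c)) and
        its Wald CI coincides with the Woolf interval."""
        for _ in range(25):
            t = TwoByTwo(*(int(v) for v in rng.integers(3, 120, size=4)))
            df = _binary_frame(t)
            X = np.column_stack([np.ones(len(df)), df["x"]])
            m = fit_logistic(df["y"], X, ["intercept", "x"])
            assert m.converged
            or_, lo, hi = odds_ratio(t)
            assert m.coef("x") == pytest.approx(math.log(or_), abs=1e-8)
            ci = m.wald_ci("x")
            assert math.exp(ci[0]) == pytest.approx(lo, rel=1e-6)
            assert math.exp(ci[1]) == pytest.approx(hi, rel=1e-6)

    def test_intercept_only_is_logit_prevalence(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        m = fit_logistic(y, np.ones((10, 1)), ["intercept"])
        assert m.coef("intercept") == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)

    def test_separation_flagged(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        m = fit_logistic(y, np.column_stack([np.ones(6), x]))
        assert not m.converged
        assert "separation" in m.diagnostic or "convergence" in m.diagnostic

    def test_collinear_design_named(self, scored_cohort):
        X, names = build_design(scored_cohort, ["age", "sex"])
        X = np.column_stack([X, X[:, 1]])  # duplicate the age column
        with pytest.raises(InferenceError, match="collinear"):
            fit_logistic(np.zeros(len(X)) + (X[:, 1] > 82), X,
                         names + ["age_copy"])

    def test_score_equations_hold_at_optimum(self, scored_cohort, rng):
        df = scored_cohort.assign(y=(rng.uniform(size=len(scored_cohort)) < 0.3).astype(int))
        X, names = build_design(df, ["age", "sex", "polypharmacy", "gp_opinion"])
        m = fit_logistic(df["y"], X, names)
        assert m.converged
        resid = df["y"].to_numpy() - predicted_risk(m, X)
        assert np.max(np.abs(X.T @ resid)) < 1e-6

    def test_order_invariance_and_age_rescaling(self, scored_cohort, rng):
        df = scored_cohort.assign(y=(rng.uniform(size=len(scored_cohort)) < 0.25).astype(int))
        m1 = fit_model(df, "y", ["age", "sex"])
        m2 = fit_model(df.sample(frac=1, random_state=3), "y", ["age", "sex"])
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-7)
        df10 = df.assign(age=df["age"] / 10.0)
        m3 = fit_model(df10, "y", ["age", "sex"])
        assert m3.coef("age") == pytest.approx(10.0 * m1.coef("age"), rel=1e-6)

    def test_matches_statsmodels(self, scored_cohort, rng):
        """Independent cross-check of the IRLS fit against statsmodels."""
        import statsmodels.api as sm

        df = scored_cohort.assign(y=(rng.uniform(size=len(scored_cohort)) < 0.3).astype(int))
        X, names = build_design(df, ["age", "sex", "polypharmacy", "multimorbidity",
                                     "living", "gp_opinion", "iscope_score"])
        ours = fit_logistic(df["y"], X, names)
        ref = sm.Logit(df["y"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(ours.covariance)), ref.bse, rtol=1e-5
        )

    def test_nested_models_never_lose_likelihood(self, scored_cohort, rng):
        df = scored_cohort.assign(y=(rng.uniform(size=len(scored_cohort)) < 0.3).astype(int))
        small = fit_model(df, "y", ["age", "sex"])
        big = fit_model(df, "y", ["age", "sex", "gp_opinion"])
        assert big.log_likelihood >= small.log_likelihood - 1e-9


class TestNagelkerke:
    def _model(self, l1, l0, n):
        return FittedModel(
            term_names=["intercept"], coefficients=np.zeros(1),
            covariance=np.zeros((1, 1)), log_likelihood=l1,
            null_log_likelihood=l0, n_obs=n, converged=True, n_iter=1,
        )

    def test_no_improvement_is_zero(self):
        assert nagelkerke_r2(self._model(-10.0, -10.0, 30)) == 0.0

    def test_perfect_prediction_is_one(self):
        assert nagelkerke_r2(self._model(0.0, -20.0, 30)) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """n=4, y=(1,1,0,0), fitted p=(.8,.8,.2,.2) vs null .5:
        L1=4 ln .8, L0=4 ln .5; R2_CS=1-.152588^.5=.609375, max=.75."""
        l1 = 4 * math.log(0.8)
        l0 = 4 * math.log(0.5)
        assert nagelkerke_r2(self._model(l1, l0, 4)) == pytest.approx(0.8125)

    def test_empty_model_rejected(self):
        with pytest.raises(InferenceError):
            nagelkerke_r2(self._model(-1.0, -1.0, 0))


class TestPredictedRisk:
    def test_zero_coefficients_give_half(self):
        m = FittedModel(["intercept", "x"], np.zeros(2), np.eye(2), -1.0, -1.0,
                        4, True, 1)
        np.testing.assert_allclose(predicted_risk(m, [[1.0, 3.0]]), [0.5])

    def test_monotone_in_positive_coefficient(self):
        m = FittedModel(["intercept", "x"], np.array([0.0, 1.5]), np.eye(2),
                        -1.0, -1.0, 4, True, 1)
        r = predicted_risk(m, [[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        assert np.all(np.diff(r) > 0)

    def test_missing_term_named(self):
        m = FittedModel(["intercept", "x"], np.zeros(2), np.eye(2), -1.0, -1.0,
                        4, True, 1)
        with pytest.raises(InferenceError, match="x"):
            predicted_risk(m, [[1.0]])
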
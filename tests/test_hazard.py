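import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

import pathmed as pm


def _sim_exp_cox(rng, n=2000, beta=(0.5, -0.3), base=0.1, cens=8.0):
    X = rng.normal(size=(n, len(beta)))
    T = rng.exponential(1.0 / (base * np.exp(X @ np.array(beta))))
    C = rng.exponential(cens, n)
    return X, np.minimum(T, C), T <= C


class TestCox:
    def test_breslow_jumps_on_four_patient_toy(self):
        # events at t=1 (x=1, all four at risk) and t=2 (x=0, three at risk):
        # baseline jumps are 1/(2e^b + 2) and 1/(e^b + 2)
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 0])
        fit = pm.fit_cox(X, t, e)
        b = fit.coef[0]
        assert fit.cumhaz0(1.0) == pytest.approx(1.0 / (2 * np.exp(b) + 2))
        assert fit.cumhaz0(2.5) == pytest.approx(
            1.0 / (2 * np.exp(b) + 2) + 1.0 / (np.exp(b) + 2))
        assert fit.cumhaz0(0.9) == 0.0

    def test_coefficient_recovery_and_lifelines_agreement(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        X, t, e = _sim_exp_cox(rng)
        fit = pm.fit_cox(X, t, e, names=["a", "b"])
        # recovery under correct specification: within 3 SE (SE ~ 1/sqrt(events))
        se = 1.0 / np.sqrt(e.sum())
        assert np.all(np.abs(fit.coef - [0.5, -0.3]) < 3 * se)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "a": X[:, 0], "b": X[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-5)

    def test_constant_covariate_dropped_with_nelson_aalen_baseline(self, rng):
        t = rng.exponential(1.0, 50) + 0.0
        e = np.ones(50, bool)
        with pytest.warns(UserWarning, match="constant"):
            fit = pm.fit_cox(np.ones((50, 1)), t, e)
        assert fit.coef[0] == 0.0
        # with no covariates the Breslow baseline is the Nelson-Aalen estimator
        ts = np.sort(t)
        na = np.cumsum(1.0 / (50 - np.arange(50)))
        assert fit.cumhaz0(ts[10]) == pytest.approx(na[10])

    def test_no_events_yields_zero_hazard(self):
        with pytest.warns(UserWarning, match="no events"):
            fit = pm.fit_cox(np.zeros((5, 0)), np.arange(1.0, 6.0), np.zeros(5, int))
        assert np.all(pm.predict_interval_survival(fit, np.zeros((3, 0)), 4.0) == 1.0)

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=(100, 1))
        X = np.hstack([x, 2 * x])
        t = rng.exponential(1.0, 100)
        with pytest.raises(pm.FitError, match="collinear"):
            pm.fit_cox(X, t, np.ones(100, bool))

    def test_left_truncated_baseline_anchored_at_entry(self, rng):
        t = 3.0 + rng.exponential(2.0, 200)
        fit = pm.fit_cox(np.zeros((200, 0)), t, np.ones(200, bool), entry_time=3.0)
        assert fit.cumhaz0(3.0) == 0.0
        assert fit.entry_time == 3.0
        with pytest.raises(ValueError):
            fit.cumhaz0(2.0)


class TestSurvivalPrediction:
    def test_worked_example_terminal_prediction(self):
        # printed inputs: Lambda0(5)=0.06, log hazard ratios (0.02, 0.05, -0.05)
        fit = pm.HazardFit(np.array([0.02, 0.05, -0.05]), ["m1", "l0", "l1"],
                           np.array([5.0]), np.array([0.06]), entry_time=3.0)
        p = pm.predict_interval_survival(fit, [[63.36, 62.79, 62.36]], 5.0)
        assert p[0] == pytest.approx(np.exp(-0.06 * np.exp(1.2887)), abs=1e-4)
        assert p[0] == pytest.approx(0.804, abs=5e-4)

    def test_worked_example_visit_survival(self):
        fit = pm.HazardFit(np.array([0.003]), ["l0"], np.array([3.0]),
                           np.array([0.02]), entry_time=0.0)
        p = pm.predict_interval_survival(fit, [[62.79]], 3.0)
        assert p[0] == pytest.approx(0.976, abs=5e-4)

    @given(st.floats(0.5, 10), st.floats(0.5, 10))
    def test_nonincreasing_in_time(self, t1, t2):
        fit = pm.HazardFit(np.array([0.1]), ["x"], np.array([1.0, 2.0, 5.0]),
                           np.array([0.05, 0.4, 1.1]), entry_time=0.0)
        lo, hi = sorted((t1, t2))
        x = [[1.3]]
        assert pm.predict_interval_survival(fit, x, hi) <= \
            pm.predict_interval_survival(fit, x, lo) + 1e-15

    def test_zero_coefficients_reduce_to_baseline_survival(self, rng):
        t = rng.exponential(2.0, 300)
        fit = pm.fit_cox(np.zeros((300, 0)), t, np.ones(300, bool))
        p = pm.predict_interval_survival(fit, np.zeros((1, 0)), 1.0)
        assert p[0] == pytest.approx(np.exp(-fit.cumhaz0(1.0)))

    def test_dimension_mismatch(self):
        fit = pm.HazardFit(np.array([0.1, 0.2]), ["a", "b"], np.array([1.0]),
                           np.array([0.1]))
        with pytest.raises(ValueError, match="columns"):
            pm.predict_interval_survival(fit, [[1.0]], 1.0)


class TestQuasibinomialLogit:
    def test_noiseless_coefficients_recovered(self, rng):
        x = rng.normal(size=(500, 1))
        y = expit(0.5 + 1.2 * x[:, 0])
        fit = pm.fit_quasibinomial_logit(x, y)
        np.testing.assert_allclose(fit.params, [0.5, 1.2], atol=1e-6)

    def test_fitted_mean_matches_response_mean(self, rng):
        # holds under arbitrary misspecification: score equation with intercept
        x = rng.normal(size=(400, 2))
        y = expit(0.3 + 0.8 * x[:, 0] + 0.5 * x[:, 0] ** 2)  # model omits the square
        fit = pm.fit_quasibinomial_logit(x, y)
        preds = pm.predict_logit(fit, x)
        assert preds.mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_constant_response_gives_intercept_only_fit(self, rng):
        x = rng.normal(size=(50, 3))
        fit = pm.fit_quasibinomial_logit(x, np.full(50, 0.37))
        np.testing.assert_allclose(pm.predict_logit(fit, x), 0.37, atol=1e-12)

    def test_worked_example_predictions(self):
        med = pm.LogitFit(np.array([1.48, 0.049, -0.051]), ["l0", "l1"])
        assert pm.predict_logit(med, [[62.79, 62.63]])[0] == pytest.approx(0.796, abs=5e-4)
        conf = pm.LogitFit(np.array([1.71, -0.003]), ["l0"])
        assert pm.predict_logit(conf, [[62.79]])[0] == pytest.approx(
            expit(1.52163), abs=1e-5)
        assert round(float(pm.predict_logit(conf, [[62.79]])[0]), 2) == 0.82

    def test_zero_model_predicts_half(self):
        fit = pm.LogitFit(np.zeros(3), ["a", "b"])
        assert pm.predict_logit(fit, [[5.0, -2.0]])[0] == pytest.approx(0.5)

    def test_monotone_in_covariate_by_coefficient_sign(self):
        fit = pm.LogitFit(np.array([0.2, 0.7, -0.4]), ["up", "down"])
        lo = pm.predict_logit(fit, [[0.0, 1.0]])[0]
        assert pm.predict_logit(fit, [[1.0, 1.0]])[0] > lo
        assert pm.predict_logit(fit, [[0.0, 2.0]])[0] < lo

    def test_responses_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            pm.fit_quasibinomial_logit(np.zeros((3, 1)), np.array([0.1, 1.2, 0.5]))

    def test_fractional_and_binary_responses_accepted(self, rng):
        x = rng.normal(size=(200, 1))
        y = (rng.uniform(size=200) < expit(x[:, 0])).astype(float)  # exact 0/1
        fit = pm.fit_quasibinomial_logit(x, y)
        assert 0.5 < fit.params[1] < 1.6
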
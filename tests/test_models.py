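"""Scaling, count/latency/time-trend fits and the delta-AIC rule."""

import numpy as np
import pandas as pd
import pytest

from metabehave import (
    ModelFit,
    compare_models,
    fit_censored_latency_model,
    fit_linear_model,
    fit_lmm_time_trend,
    fit_nb_regression,
    scale,
)
from metabehave.models import ModelError
from metabehave.repeatability import LatencyRecord


class TestScale:
    def test_arithmetic(self):
        s = scale([1.0, 2.0, 3.0])
        assert np.allclose(s.values, [-1.0, 0.0, 1.0])
        assert s.center == 2.0 and s.spread == 1.0

    def test_idempotent(self):
        s = scale([4.0, -2.0, 7.0, 1.0])
        again = scale(s.values)
        assert np.allclose(again.values, s.values, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ModelError, match="constant"):
            scale([3.0, 3.0, 3.0])


class TestNBRegression:
    def test_intercept_only_mle_is_log_mean(self):
        y = np.array([2, 5, 7, 1, 9, 4, 6, 3])
        fit = fit_nb_regression(y)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(y.mean()),
                                                              abs=1e-5)

    def test_poisson_limit(self):
        """At zero dispersion the NB likelihood equals Poisson regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        y = rng.poisson(np.exp(1.0 + 0.4 * x))
        fit = fit_nb_regression(y, x, alpha=0.0)
        X = np.column_stack([np.ones_like(x), x])
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.loglik == pytest.approx(float(ref.llf), abs=1e-4)

    def test_slope_recovery(self):
        """Known log-link slope recovered from overdispersed counts."""
        rng = np.random.default_rng(2)
        n = 500
        x = rng.normal(size=n)
        mu = np.exp(1.2 + 0.5 * x)
        alpha_true = 0.3
        y = rng.negative_binomial(1 / alpha_true, 1 / (1 + alpha_true * mu))
        fit = fit_nb_regression(y, x)
        assert fit.coefficients["x0"] == pytest.approx(0.5, abs=0.12)
        assert fit.coefficients["alpha"] == pytest.approx(alpha_true, abs=0.15)

    def test_aic_identity(self):
        y = np.array([2, 5, 7, 1, 9, 4, 6, 3])
        fit = fit_nb_regression(y)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)


class TestLMMTimeTrend:
    @pytest.fixture
    def trended(self):
        rng = np.random.default_rng(3)
        days = np.tile(np.arange(6, dtype=float), 12)
        chicks = np.repeat([f"c{i}" for i in range(12)], 6)
        y = (0.4 * days + rng.normal(0, 0.6, 12)[
            pd.Categorical(chicks).codes] + rng.normal(0, 0.3, 72))
        return y, days, chicks

    def test_positive_slope_detected(self, trended):
        y, days, chicks = trended
        null = fit_lmm_time_trend(y, None, chicks, name="null_model")
        cand = fit_lmm_time_trend(y, days, chicks, name="time")
        assert cand.coefficients["time"] > 0.3
        comp = compare_models([null, cand])
        assert comp.selected == "time"
        assert comp.delta_aic > 10

    def test_zero_slope_keeps_null(self):
        rng = np.random.default_rng(4)
        days = np.tile(np.arange(6, dtype=float), 12)
        chicks = np.repeat([f"c{i}" for i in range(12)], 6)
        y = rng.normal(0, 0.5, 12)[pd.Categorical(chicks).codes] + rng.normal(
            0, 0.4, 72
        )
        null = fit_lmm_time_trend(y, None, chicks, name="null_model")
        cand = fit_lmm_time_trend(y, days, chicks, name="time")
        assert compare_models([null, cand]).selected == "null_model"

    def test_no_group_variance_matches_ols(self):
        """With no between-chick spread the slope equals plain OLS."""
        rng = np.random.default_rng(5)
        days = np.tile(np.arange(8, dtype=float), 4)
        chicks = np.repeat(list("abcd"), 8)
        y = 1.0 + 0.25 * days + rng.normal(0, 0.2, 32)
        fit = fit_lmm_time_trend(y, days, chicks)
        slope_ols = np.polyfit(days, y, 1)[0]
        assert fit.coefficients["time"] == pytest.approx(slope_ols, abs=1e-3)


def _records(latencies, censored=None):
    censored = censored or [False] * len(latencies)
    return [
        LatencyRecord("c%d" % i, "boldness", "pre_RAM", i, t, c)
        for i, (t, c) in enumerate(zip(latencies, censored))
    ]


class TestCensoredLatencyModel:
    def test_exponential_closed_form(self):
        """Shape fixed at 1 and no censoring: the fitted rate is n / sum t."""
        t = [12.0, 44.0, 7.0, 90.0, 33.0, 61.0]
        fit = fit_censored_latency_model(_records(t), shape=1.0)
        assert fit.coefficients["intercept"] == pytest.approx(
            np.log(np.sum(t) / len(t)), abs=1e-5
        )
        # analytic exponential loglik at the MLE: -n*(log(mean) + 1)
        assert fit.loglik == pytest.approx(
            -len(t) * (np.log(np.mean(t)) + 1.0), abs=1e-6
        )

    def test_matches_lifelines(self):
        """Dual-route check against an independent AFT implementation."""
        from lifelines import WeibullAFTFitter

        rng = np.random.default_rng(6)
        x = rng.normal(size=120)
        t = rng.weibull(1.4, 120) * np.exp(4.0 + 0.5 * x)
        cens = t > 600.0
        t = np.minimum(t, 600.0)
        records = [
            LatencyRecord(f"c{i}", "boldness", "pre_RAM", i, float(ti), bool(ci))
            for i, (ti, ci) in enumerate(zip(t, cens))
        ]
        mine = fit_censored_latency_model(records, predictor=x)
        frame = pd.DataFrame({"t": t, "e": (~cens).astype(int), "x": x})
        ref = WeibullAFTFitter().fit(frame, duration_col="t", event_col="e")
        assert mine.loglik == pytest.approx(float(ref.log_likelihood_), abs=1e-3)
        assert mine.coefficients["rmr"] == pytest.approx(
            float(ref.params_[("lambda_", "x")]), abs=1e-3
        )

    def test_all_censored_rejected(self):
        with pytest.raises(ModelError, match="censored"):
            fit_censored_latency_model(
                _records([600.0, 600.0], censored=[True, True])
            )

    def test_null_effect_rarely_selected(self):
        """With no true predictor effect the AIC rule keeps the null in
        the vast majority of replicates."""
        rng = np.random.default_rng(7)
        picks = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.normal(size=70)
            t = rng.weibull(1.3, 70) * 130.0
            cens = t > 600.0
            t = np.minimum(t, 600.0)
            records = [
                LatencyRecord(f"c{i}", "boldness", "pre_RAM", i, float(ti), bool(ci))
                for i, (ti, ci) in enumerate(zip(t, cens))
            ]
            null = fit_censored_latency_model(records, name="null_model")
            cand = fit_censored_latency_model(records, predictor=x, name="rmr")
            if compare_models([null, cand]).selected == "rmr":
                picks += 1
        assert picks <= 10

    def test_strong_effect_selected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        t = rng.weibull(1.3, 80) * np.exp(4.5 + 1.2 * x)
        cens = t > 600.0
        t = np.minimum(t, 600.0)
        records = [
            LatencyRecord(f"c{i}", "boldness", "pre_RAM", i, float(ti), bool(ci))
            for i, (ti, ci) in enumerate(zip(t, cens))
        ]
        null = fit_censored_latency_model(records, name="null_model")
        cand = fit_censored_latency_model(records, predictor=x, name="rmr")
        assert compare_models([null, cand]).selected == "rmr"


class TestCompareModels:
    def _fit(self, name, loglik, k, response="y"):
        return ModelFit(name=name, loglik=loglik, k=k, response=response)

    @pytest.mark.parametrize(
        "delta, expected",
        [(1.80, "null_model"), (11.64, "candidate"), (2.00, "candidate")],
    )
    def test_threshold_rule(self, delta, expected):
        """1.80 keeps the null; 11.64 and the exact 2.00 boundary prefer
        the candidate."""
        null = self._fit("null_model", loglik=-100.0, k=1)
        cand = self._fit("candidate", loglik=-100.0 + (delta + 2.0) / 2.0, k=2)
        comp = compare_models([null, cand])
        assert comp.delta_aic == pytest.approx(delta)
        assert comp.selected == expected

    def test_nesting_monotonicity(self):
        """Adding an irrelevant predictor never lowers the loglik."""
        rng = np.random.default_rng(9)
        y = rng.normal(2.0, 1.0, 60)
        junk = rng.normal(size=60)
        assert (
            fit_linear_model(y, junk).loglik >= fit_linear_model(y).loglik - 1e-9
        )
        counts = rng.poisson(6.0, 60)
        assert (
            fit_nb_regression(counts, junk).loglik
            >= fit_nb_regression(counts).loglik - 1e-6
        )

    def test_mixed_responses_rejected(self):
        with pytest.raises(ModelError, match="different responses"):
            compare_models(
                [self._fit("a", -10, 1, "y1"), self._fit("b", -9, 2, "y2")]
            )

    def test_nonconverged_excluded(self):
        bad = ModelFit("bad", -5.0, 2, converged=False, response="y")
        with pytest.warns(UserWarning, match="converge"), pytest.raises(
            ModelError
        ):
            compare_models([self._fit("a", -10, 1), bad])
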
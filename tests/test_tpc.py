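"""TPC model registry, fitting, AICc ranking, derived parameters, bootstrap."""

import math

import numpy as np
import pytest

from gametherm import tpc
from gametherm.tpc import (
    MODEL_REGISTRY,
    TPCDataset,
    aicc,
    bootstrap_cis,
    derive_params,
    evaluate_model,
    fit_model,
    get_model,
    rank_models,
)
from conftest import simulate_binomial_tpc


def make_dataset(temps, rates, name="trait"):
    return TPCDataset(name, np.asarray(temps, float), np.asarray(rates, float))


class TestEvaluateModel:
    def test_gaussian_peak_value_and_symmetry(self):
        params = [0.95, 17.6, 5.0]
        assert evaluate_model("gaussian", params, 17.6) == pytest.approx(0.95)
        for delta in (0.5, 3.0, 11.0):
            left = evaluate_model("gaussian", params, 17.6 - delta)
            right = evaluate_model("gaussian", params, 17.6 + delta)
            assert left == pytest.approx(right, rel=1e-12)

    def test_quadratic_matches_hand_polynomial(self):
        a, b, c = 0.3, 0.08, -0.004
        grid = np.linspace(0, 40, 23)
        expected = a + b * grid + c * grid**2
        assert np.allclose(evaluate_model("quadratic", [a, b, c], grid),
                           expected, atol=1e-12)

    def test_modified_gaussian_reduces_to_gaussian_at_b2(self):
        grid = np.linspace(0, 40, 41)
        g = evaluate_model("gaussian", [1.0, 15.0, 6.0], grid)
        mg = evaluate_model("modifiedgaussian", [1.0, 15.0, 6.0, 2.0], grid)
        assert np.allclose(g, mg, rtol=1e-12)

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="unknown TPC model"):
            get_model("parabola")

    @pytest.mark.parametrize("name", sorted(MODEL_REGISTRY))
    def test_registry_models_finite_and_unimodalish(self, name):
        """Every registered model evaluates finite with its own start heuristic
        over a realistic assay grid."""
        spec = MODEL_REGISTRY[name]
        t = np.linspace(8, 38, 31)
        r = evaluate_model("gaussian", [0.9, 17.0, 6.0], t)
        params = np.asarray(spec.guess_fn(t, r), dtype=float)
        lo, hi = spec.bounds_fn(t, r)
        assert np.all(np.asarray(lo) < np.asarray(hi))
        vals = evaluate_model(spec, np.clip(params, lo, hi), t)
        assert np.all(np.isfinite(vals))

    def test_scalar_and_vector_agree(self):
        params = [0.9, 16.0, 5.0]
        grid = np.array([8.0, 16.0, 30.0])
        vec = evaluate_model("gaussian", params, grid)
        assert vec[1] == pytest.approx(evaluate_model("gaussian", params, 16.0))


class TestAicc:
    def test_closed_form_value(self):
        # frozen from the Gaussian log-likelihood closed form:
        # -2*(-n/2*(ln 2pi + ln(rss/n) + 1)) + 2k + 2k(k+1)/(n-k-1)
        assert aicc(1.0, 10, 3) == pytest.approx(15.35292, abs=5e-6)

    def test_monotone_in_rss(self):
        assert aicc(2.0, 10, 3) > aicc(1.0, 10, 3)

    def test_boundary_excluded(self):
        with pytest.raises(ValueError, match="n - k - 1"):
            aicc(1.0, 4, 3)

    def test_recompute_via_independent_loglik(self):
        rss, n, k = 0.37, 36, 4
        loglik = -n / 2 * (math.log(2 * math.pi) + math.log(rss / n) + 1)
        expected = -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(rss, n, k) == pytest.approx(expected, rel=1e-12)


class TestFitModel:
    def test_noiseless_gaussian_recovery(self):
        temps = np.repeat(np.linspace(8, 38, 12), 3)
        rates = evaluate_model("gaussian", [0.95, 17.6, 6.0], temps)
        fit = fit_model(make_dataset(temps, rates), "gaussian", n_starts=6, seed=0)
        assert fit.converged
        assert fit.estimates[1] == pytest.approx(17.6, abs=1e-3)
        assert fit.estimates[0] == pytest.approx(0.95, abs=1e-4)

    def test_rss_equals_residual_sum_at_estimates(self):
        t, r = simulate_binomial_tpc(seed=5)
        data = make_dataset(t, r)
        fit = fit_model(data, "gaussian", n_starts=4, seed=1)
        resid = fit.predict(t) - r
        assert fit.rss == pytest.approx(float(np.sum(resid**2)), rel=1e-12)

    def test_same_seed_identical_estimates(self):
        t, r = simulate_binomial_tpc(seed=6)
        data = make_dataset(t, r)
        f1 = fit_model(data, "modifiedgaussian", n_starts=6, seed=11)
        f2 = fit_model(data, "modifiedgaussian", n_starts=6, seed=11)
        assert np.array_equal(f1.estimates, f2.estimates)

    def test_constant_rate_degenerate_input(self):
        temps = np.linspace(8, 38, 12)
        data = make_dataset(temps, np.full(12, 0.5))
        fit = fit_model(data, "gaussian", n_starts=6, seed=0)
        # flat data: either the flat limit (rss ~ 0) or a degenerate flag
        assert (not fit.converged) or fit.rss == pytest.approx(0.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_model(make_dataset([1, 2, 3, 4, 5], [1, 2, 3, 2, 1]),
                      "modifiedgaussian")


class TestRankModels:
    def test_single_candidate_is_rank_one(self):
        t, r = simulate_binomial_tpc(seed=2)
        ranked = rank_models(make_dataset(t, r), ["gaussian"], seed=0, n_starts=4)
        assert len(ranked) == 1 and ranked[0].model.name == "gaussian"

    def test_order_invariance(self):
        t, r = simulate_binomial_tpc(seed=3)
        data = make_dataset(t, r)
        names = ["quadratic", "gaussian", "modifiedgaussian"]
        r1 = rank_models(data, names, seed=9, n_starts=6)
        r2 = rank_models(data, names[::-1], seed=9, n_starts=6)
        assert [f.model.name for f in r1] == [f.model.name for f in r2]
        assert np.allclose([f.aicc for f in r1], [f.aicc for f in r2])

    def test_overparameterized_model_excluded_not_ranked(self):
        # 6 points, modifiedgaussian has k = 5 -> n - k - 1 = 0: excluded
        t = np.array([8, 14, 17, 20, 26, 32], dtype=float)
        r = evaluate_model("gaussian", [0.9, 17.0, 6.0], t)
        r = r + np.array([1e-3, -1e-3, 2e-3, -2e-3, 1e-3, -1e-3])
        ranked, excluded = rank_models(make_dataset(t, r),
                                       ["gaussian", "modifiedgaussian"],
                                       seed=0, n_starts=4, return_excluded=True)
        assert [f.model.name for f in ranked] == ["gaussian"]
        assert excluded and excluded[0][0] == "modifiedgaussian"


class TestDeriveParams:
    def fit_gaussian(self, a=5.0):
        temps = np.repeat(np.linspace(5, 35, 13), 2)
        rates = evaluate_model("gaussian", [0.9, 20.0, a], temps)
        return fit_model(make_dataset(temps, rates), "gaussian", n_starts=4, seed=0)

    def test_breadth_matches_closed_form(self):
        # gaussian width a: region above frac f of the peak has width
        # 2a*sqrt(2*ln(1/f)); at f = 0.8 that is 2a*sqrt(2 ln 1.25)
        fit = self.fit_gaussian(a=5.0)
        der = derive_params(fit, 0.0, 40.0, 0.05, threshold=0.8)
        expected = 2 * 5.0 * math.sqrt(2 * math.log(1.25))
        assert der.t_br == pytest.approx(expected, abs=0.01)
        assert der.contiguous and not der.boundary_censored

    def test_rmax_topt_located(self):
        fit = self.fit_gaussian()
        der = derive_params(fit, 0.0, 40.0, 0.05)
        assert der.t_opt == pytest.approx(20.0, abs=1e-3)
        assert der.r_max == pytest.approx(0.9, abs=1e-6)
        grid = np.arange(0, 40.0001, 0.05)
        assert der.r_max >= np.max(np.maximum(fit.predict(grid), 0)) - 1e-9

    def test_breadth_shrinks_to_zero_as_threshold_to_one(self):
        fit = self.fit_gaussian()
        widths = [derive_params(fit, 0, 40, 0.05, threshold=thr).t_br
                  for thr in (0.8, 0.95, 0.999)]
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 0.5

    def test_breadth_region_contains_topt(self):
        t, r = simulate_binomial_tpc(seed=8)
        fit = fit_model(make_dataset(t, r), "gaussian", n_starts=4, seed=0)
        der = derive_params(fit, 5, 41, 0.05)
        val_at_topt = max(fit.predict(der.t_opt), 0.0)
        assert val_at_topt >= der.breadth_threshold * der.r_max - 1e-9

    def test_monotone_curve_boundary_censored(self):
        temps = np.linspace(5, 25, 11)
        rates = 0.02 * temps
        fit = fit_model(make_dataset(temps, rates), "quadratic", n_starts=4, seed=0)
        der = derive_params(fit, 5, 25, 0.05)
        assert der.boundary_censored
        assert der.t_opt == pytest.approx(25.0, abs=0.01)

    def test_quadratic_negative_tails_clamped(self):
        # downward parabola crossing zero: breadth must not count negative tails
        temps = np.linspace(0, 30, 16)
        rates = evaluate_model("quadratic", [-0.5, 0.2, -0.0067], temps)
        fit = fit_model(make_dataset(temps, rates), "quadratic", n_starts=4, seed=0)
        der = derive_params(fit, 0, 30, 0.05)
        assert der.r_max > 0
        assert 0 < der.t_br < 30


class TestBootstrap:
    def test_noiseless_data_zero_width_intervals(self):
        temps = np.repeat(np.linspace(8, 32, 9), 2)
        rates = evaluate_model("gaussian", [0.9, 18.0, 6.0], temps)
        fit = fit_model(make_dataset(temps, rates), "gaussian", n_starts=4, seed=0)
        boot = bootstrap_cis(make_dataset(temps, rates), fit, n_boot=100, seed=1)
        lo, hi = boot.derived.ci["t_opt"]
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_identical_intervals(self):
        t, r = simulate_binomial_tpc(seed=4)
        data = make_dataset(t, r)
        fit = fit_model(data, "gaussian", n_starts=4, seed=0)
        b1 = bootstrap_cis(data, fit, n_boot=100, seed=77)
        b2 = bootstrap_cis(data, fit, n_boot=100, seed=77)
        assert b1.derived.ci == b2.derived.ci
        assert b1.parameter_cis == b2.parameter_cis

    def test_interval_brackets_estimate(self):
        t, r = simulate_binomial_tpc(seed=10)
        data = make_dataset(t, r)
        fit = fit_model(data, "gaussian", n_starts=4, seed=0)
        boot = bootstrap_cis(data, fit, n_boot=200, seed=5)
        lo, hi = boot.derived.ci["t_opt"]
        assert lo <= boot.derived.t_opt <= hi
        assert boot.failure_rate < 0.5 and not boot.unreliable

    def test_small_n_boot_rejected(self):
        t, r = simulate_binomial_tpc(seed=4)
        data = make_dataset(t, r)
        fit = fit_model(data, "gaussian", n_starts=4, seed=0)
        with pytest.raises(ValueError):
            bootstrap_cis(data, fit, n_boot=50)
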
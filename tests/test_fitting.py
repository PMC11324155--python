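"""Least-squares fitting with dormancy time: objective, recovery, policy."""

import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from organoidgrowth.fitting import (
    PHI2_FLOOR,
    CellNumberSeries,
    classify_exponential,
    fit_cohort,
    fit_organoid,
    log_likelihood,
    sse_objective,
)
from organoidgrowth.models import B_FLOOR, GrowthModelSpec, evaluate_trajectory

EXP = GrowthModelSpec("exponential")
GOMP = GrowthModelSpec("gompertz")
LN2 = math.log(2)


class TestObjective:
    def test_zero_on_the_curve(self, exp_series):
        assert sse_objective(EXP, [LN2], 1.0, exp_series) == pytest.approx(0.0)

    def test_direct_arithmetic(self, exp_series):
        # predictions at tau=0: (1, 8, 32); residuals (1, 8, 32)
        assert sse_objective(EXP, [LN2], 0.0, exp_series) == pytest.approx(1089.0)

    def test_overflow_returns_penalty_not_crash(self):
        s = CellNumberSeries("big", [0.0, 3.0, 5.0], [1.0, 2.0, 3.0])
        val = sse_objective(EXP, [10.0], 4.0, s)
        assert np.isfinite(val) and val > 1e10

    def test_invalid_tau(self, exp_series):
        with pytest.raises(ValueError):
            sse_objective(EXP, [LN2], -0.1, exp_series)


class TestLogLikelihood:
    def test_residual_term_vanishes(self, exp_series):
        ll = log_likelihood(EXP, [LN2], 1.0, 1.0, exp_series)
        assert ll == pytest.approx(-1.5 * math.log(2 * math.pi), abs=1e-12)

    def test_sigma_mle_is_phi2_over_k(self, exp_series):
        phi2 = sse_objective(EXP, [LN2], 0.0, exp_series)
        k = exp_series.k
        sigmas = np.linspace(0.3, 3.0, 40) * math.sqrt(phi2 / k)
        lls = [log_likelihood(EXP, [LN2], 0.0, s, exp_series) for s in sigmas]
        best = sigmas[int(np.argmax(lls))]
        assert best == pytest.approx(math.sqrt(phi2 / k), rel=0.05)

    def test_formula_at_two_sigmas(self, exp_series):
        phi2 = sse_objective(EXP, [LN2], 0.0, exp_series)
        for sigma in (1.0, 2.0):
            expected = (-1.5 * math.log(2 * math.pi * sigma**2)
                        - phi2 / (2 * sigma**2))
            got = log_likelihood(EXP, [LN2], 0.0, sigma, exp_series)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_sigma_domain(self, exp_series):
        with pytest.raises(ValueError):
            log_likelihood(EXP, [LN2], 0.0, 0.0, exp_series)


class TestFitOrganoid:
    def test_noise_free_exponential_recovery(self, exp_series):
        fit = fit_organoid(exp_series, EXP, tau_max=4.0, n_starts=20, seed=1)
        assert fit.params["a"] == pytest.approx(LN2, abs=1e-4)
        assert fit.tau_hat == pytest.approx(1.0, abs=1e-3)
        assert fit.phi2 == PHI2_FLOOR
        assert fit.sigma2_hat == pytest.approx(PHI2_FLOOR / 3)

    def test_noise_free_gompertz_k4_recovery(self):
        a, b, tau = 1.1, 0.3, 1.7
        days = np.array([0.0, 1.0, 3.0, 6.0])
        counts = evaluate_trajectory(GOMP, [a, b], 1.0, tau + days).values
        s = CellNumberSeries("g", days, counts)
        fit = fit_organoid(s, GOMP, tau_max=7.0, n_starts=50, seed=2)
        assert fit.phi2 == PHI2_FLOOR
        assert fit.params["a"] == pytest.approx(a, rel=0.01)
        assert fit.params["b"] == pytest.approx(b, rel=0.01)
        assert fit.tau_hat == pytest.approx(tau, rel=0.01)

    def test_scipy_cross_check(self):
        """The in-package optimizer reaches the same optimum as an
        independent scipy bounded least-squares polish."""
        a, b, tau = 0.9, 0.2, 2.0
        days = np.array([0.0, 1.0, 3.0, 6.0])
        rng = np.random.default_rng(5)
        counts = evaluate_trajectory(GOMP, [a, b], 1.0, tau + days).values
        counts = counts * (1 + 0.03 * rng.standard_normal(4))
        s = CellNumberSeries("g", days, counts)
        fit = fit_organoid(s, GOMP, tau_max=7.0, n_starts=40, seed=3)

        def resid(x):
            return s.counts - evaluate_trajectory(
                GOMP, [x[0], x[1]], 1.0, x[2] + days
            ).values

        sol = least_squares(
            resid, [fit.params["a"], fit.params["b"], fit.tau_hat],
            bounds=([1e-4, 1e-4, 0.0], [10.0, 10.0, 7.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        assert 2 * sol.cost >= fit.phi2 * (1 - 1e-6) or fit.phi2 == PHI2_FLOOR
        np.testing.assert_allclose(
            sol.x, [fit.params["a"], fit.params["b"], fit.tau_hat], rtol=1e-3
        )

    def test_determinism(self, exp_series):
        f1 = fit_organoid(exp_series, GOMP, n_starts=10, seed=7)
        f2 = fit_organoid(exp_series, GOMP, n_starts=10, seed=7)
        assert np.array_equal(f1.theta_hat, f2.theta_hat)
        assert f1.tau_hat == f2.tau_hat and f1.phi2 == f2.phi2

    def test_multistart_monotone_in_n_starts(self):
        rng = np.random.default_rng(9)
        days = np.array([0.0, 3.0, 5.0])
        counts = np.array([3.0, 40.0, 200.0]) * (1 + 0.1 * rng.standard_normal(3))
        s = CellNumberSeries("m", days, counts)
        phis = [fit_organoid(s, GOMP, n_starts=n, seed=4).phi2
                for n in (1, 3, 10, 30)]
        assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(phis, phis[1:]))

    def test_degenerate_constant_series_hits_lower_bound(self):
        s = CellNumberSeries("c", [0.0, 3.0, 5.0], [1.0, 1.0, 1.0])
        fit = fit_organoid(s, EXP, n_starts=10, seed=1)
        assert fit.params["a"] == pytest.approx(1e-4)
        assert any(flag.startswith("a:lower") for flag in fit.at_bounds)

    def test_underdetermined_series_warns(self):
        s = CellNumberSeries("u", [0.0, 3.0], [2.0, 20.0])
        with pytest.warns(UserWarning, match="datapoints"):
            fit_organoid(s, GOMP, n_starts=5, seed=1)

    def test_log_scale_fits_relative_structure(self):
        a, b, tau = 1.0, 0.25, 1.0
        days = np.array([0.0, 1.0, 3.0, 6.0])
        counts = evaluate_trajectory(GOMP, [a, b], 1.0, tau + days).values
        s = CellNumberSeries("l", days, counts)
        fit = fit_organoid(s, GOMP, tau_max=7.0, n_starts=40, seed=6, scale="log")
        assert fit.scale == "log"
        assert fit.phi2 == PHI2_FLOOR  # floor applies identically in log mode
        assert fit.params["a"] == pytest.approx(a, rel=0.01)

    def test_exponential_truth_maps_to_b_floor(self):
        days = np.array([0.0, 1.0, 3.0, 6.0])
        counts = np.exp(0.8 * (1.5 + days))  # pure exponential, tau=1.5
        s = CellNumberSeries("e", days, counts)
        fit = fit_organoid(s, GOMP, tau_max=7.0, n_starts=30, seed=8)
        assert fit.is_exponential
        assert classify_exponential(fit)


class TestClassifyExponential:
    def test_floor_and_tolerance(self):
        from conftest import make_gompertz_fit

        assert classify_exponential(make_gompertz_fit("x", 1.0, B_FLOOR))
        assert classify_exponential(
            make_gompertz_fit("x", 1.0, B_FLOOR + 1e-12))
        assert not classify_exponential(make_gompertz_fit("x", 1.0, 0.3))

    def test_rejects_non_gompertz(self, exp_series):
        fit = fit_organoid(exp_series, EXP, n_starts=3, seed=1)
        with pytest.raises(ValueError):
            classify_exponential(fit)


class TestFitCohort:
    def test_matches_fit_organoid_and_order_invariant(self):
        rng = np.random.default_rng(12)
        days = np.array([0.0, 3.0, 5.0])
        series = []
        for i in range(4):
            c = np.sort(rng.uniform(1, 200, 3))
            series.append(CellNumberSeries(f"t{i}", days, c))
        fits = fit_cohort(series, [GOMP, EXP], n_starts=6, seed=42)
        fits_rev = fit_cohort(series[::-1], [GOMP, EXP], n_starts=6, seed=42)
        by_key = {(f.track_id, f.spec.label): f for f in fits_rev}
        for f in fits:
            g = by_key[(f.track_id, f.spec.label)]
            assert np.array_equal(f.theta_hat, g.theta_hat)
            assert f.phi2 == g.phi2

        from organoidgrowth.fitting import _substream

        single = fit_organoid(series[0], GOMP, n_starts=6,
                              seed=_substream(42, "t0", 0))
        batched = next(f for f in fits
                       if f.track_id == "t0" and f.spec.label == "gompertz")
        assert np.array_equal(single.theta_hat, batched.theta_hat)
        assert single.phi2 == batched.phi2

    def test_parameter_recovery_with_noise(self):
        """Median log10 accuracy of the growth rate on a noisy cohort."""
        rng = np.random.default_rng(100)
        days = np.array([0.0, 1.0, 3.0, 6.0])
        series, truth = [], []
        for i in range(60):
            a = 10 ** rng.normal(0, 0.25)
            b = a / 5 * 10 ** rng.normal(0, 0.2)
            tau = rng.uniform(0, 7)
            n = evaluate_trajectory(GOMP, [a, b], 1.0, tau + days).values
            n = np.maximum(n * (1 + 0.02 * rng.standard_normal(4)), 1e-6)
            series.append(CellNumberSeries(f"r{i}", days, n))
            truth.append(a)
        fits = fit_cohort(series, [GOMP], tau_max=7.0, n_starts=40, seed=0)
        errs = [abs(math.log10(f.params["a"] / a))
                for f, a in zip(fits, truth)]
        assert np.median(errs) < 0.05
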
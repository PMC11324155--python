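"""Closed-form growth laws: examples, ODE-oracle agreement, limits."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from organoidgrowth.models import (
    ANALYSIS_VARIANTS,
    GrowthModelSpec,
    Trajectory,
    carrying_capacity,
    doubling_time,
    evaluate_trajectory,
    general_rhs,
    gompertz_alt_parameters,
    gompertz_limit_approximation,
    growth_rate_at,
)


class TestSpecValidation:
    def test_nine_analysis_variants(self):
        labels = [s.label for s in ANALYSIS_VARIANTS]
        assert len(labels) == 9
        assert labels.count("exponential") == 1
        assert sum(l.startswith("power_law") for l in labels) == 3
        assert sum(l.startswith("von_bertalanffy") for l in labels) == 3
        assert "gompertz" in labels and "logistic" in labels

    def test_free_parameter_counts(self):
        counts = {s.label: s.n_free_params for s in ANALYSIS_VARIANTS}
        for label, n in counts.items():
            expected = 1 if label.startswith(("exponential", "power_law")) else 2
            assert n == expected, label

    @pytest.mark.parametrize("family,gamma", [
        ("power_law", None), ("power_law", 0.9),
        ("von_bertalanffy", 0.4), ("exponential", 0.5), ("gompertz", 2 / 3),
    ])
    def test_gamma_validation(self, family, gamma):
        with pytest.raises(ValueError):
            GrowthModelSpec(family, gamma)

    def test_out_of_bounds_parameters_rejected(self):
        spec = GrowthModelSpec("gompertz")
        with pytest.raises(ValueError):
            evaluate_trajectory(spec, [20.0, 0.1], 1.0, [0, 1])
        with pytest.raises(ValueError):
            evaluate_trajectory(spec, [1.0, 0.0], 1.0, [0, 1])

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), np.array([1.0, -2.0]))


class TestClosedForms:
    @pytest.mark.parametrize("spec,params,N0,t,expected", [
        (GrowthModelSpec("exponential"), [math.log(2)], 1.0, 3.0, 8.0),
        (GrowthModelSpec("logistic"), [0.7, 100.0], 100.0, 5.0, 100.0),
        (GrowthModelSpec("power_law", 0.5), [2.0], 1.0, 3.0, 16.0),
        (GrowthModelSpec("von_bertalanffy", 2 / 3), [1.0, 1.0], 1.0, 7.0, 1.0),
    ])
    def test_pointwise_examples(self, spec, params, N0, t, expected):
        traj = evaluate_trajectory(spec, params, N0, [t])
        assert traj.values[0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("spec", ANALYSIS_VARIANTS, ids=lambda s: s.label)
    def test_ode_oracle_agreement(self, spec, rng):
        """Closed forms match adaptive integration of each family's ODE to
        1e-6 relative error (integrated in log N to control relative
        accuracy across many orders of magnitude)."""
        t_eval = np.linspace(0.0, 10.0, 21)
        for _ in range(100):
            theta = np.array([
                10 ** rng.uniform(np.log10(lo), np.log10(hi))
                for lo, hi in spec.bounds.values()
            ])
            traj = evaluate_trajectory(spec, theta, 1.0, t_eval)

            def dlogn(t, y):
                N = math.exp(y[0])
                if spec.family == "exponential":
                    dN = theta[0] * N
                elif spec.family == "power_law":
                    dN = theta[0] * N ** spec.gamma
                elif spec.family == "gompertz":
                    dN = theta[0] * math.exp(-theta[1] * t) * N
                elif spec.family == "logistic":
                    dN = theta[0] * N * (1 - N / theta[1])
                else:  # von Bertalanffy
                    dN = theta[0] * N ** spec.gamma - theta[1] * N
                return [dN / N]

            sol = solve_ivp(dlogn, (0, 10), [0.0], t_eval=t_eval,
                            rtol=1e-10, atol=1e-12, method="RK45")
            assert sol.success
            rel = np.abs(np.exp(sol.y[0]) - traj.values) / traj.values
            assert rel.max() < 1e-6, (spec.label, theta, rel.max())

    @pytest.mark.parametrize("spec", ANALYSIS_VARIANTS, ids=lambda s: s.label)
    def test_monotone_below_capacity(self, spec, rng):
        t = np.linspace(0, 10, 200)
        for _ in range(20):
            theta = np.array([
                10 ** rng.uniform(np.log10(lo), np.log10(hi))
                for lo, hi in spec.bounds.values()
            ])
            K = carrying_capacity(spec, theta, 1.0)
            if not (1.0 <= K):
                continue  # N0 above capacity: shrinking solution, skip
            v = evaluate_trajectory(spec, theta, 1.0, t).values
            assert np.all(np.diff(v) >= -1e-9 * v[:-1])

    def test_logistic_inflection_at_half_capacity(self, rng):
        """The logistic solution's growth rate peaks where N = K/2."""
        spec = GrowthModelSpec("logistic")
        for _ in range(10):
            a = 10 ** rng.uniform(-0.5, 0.5)
            K = 10 ** rng.uniform(1, 4)
            t_half = brentq(
                lambda t: evaluate_trajectory(spec, [a, K], 1.0, [t]).values[0]
                - K / 2,
                0.0, 2000.0,
            )
            t = np.linspace(max(t_half - 5, 0), t_half + 5, 2001)
            v = evaluate_trajectory(spec, [a, K], 1.0, t).values
            dv = np.gradient(v, t)
            t_peak = t[np.argmax(dv)]
            assert t_peak == pytest.approx(t_half, abs=0.05)

    def test_capacity_is_large_time_limit(self):
        cases = [
            (GrowthModelSpec("gompertz"), [1.0, 0.5]),
            (GrowthModelSpec("logistic"), [1.0, 500.0]),
            (GrowthModelSpec("von_bertalanffy", 2 / 3), [2.0, 0.5]),
        ]
        for spec, theta in cases:
            K = carrying_capacity(spec, theta, 1.0)
            v = evaluate_trajectory(spec, theta, 1.0, [1e4]).values[0]
            assert v == pytest.approx(K, rel=1e-3)


class TestLimits:
    def test_gompertz_floor_is_effectively_exponential(self):
        t = np.linspace(0, 9, 91)
        gomp = evaluate_trajectory(GrowthModelSpec("gompertz"), [1.0, 1e-4], 1.0, t)
        exp = evaluate_trajectory(GrowthModelSpec("exponential"), [1.0], 1.0, t)
        assert np.max(np.abs(gomp.values - exp.values) / exp.values) < 0.005

    def test_power_law_approaches_exponential_as_gamma_to_one(self):
        # closed form at gamma=0.999 computed inline (outside the fixed
        # analysis exponents) against the package's exponential solution
        a, q = 0.7, 1e-3
        t = np.linspace(0, 5, 51)
        pl = (1.0 + q * a * t) ** (1.0 / q)
        exp = evaluate_trajectory(GrowthModelSpec("exponential"), [a], 1.0, t)
        assert np.max(np.abs(pl - exp.values) / exp.values) < 0.01

    @pytest.mark.parametrize("epsilon,tol", [(1e-3, 0.01), (1e-4, 0.001)])
    def test_gompertz_as_limit_of_general_form(self, epsilon, tol):
        """Integrating the reparametrized general ODE for small epsilon
        reproduces the Gompertz closed form with a=c, b=d."""
        a, b, delta = 1.0, 0.2, 1.0
        c, d = gompertz_limit_approximation(delta, epsilon, a, b)
        assert c == pytest.approx(a - b)
        assert d == pytest.approx(a * epsilon)

        def rhs(t, N):
            return (c * N[0] ** delta
                    - d * N[0] ** (delta - epsilon) * (N[0] ** epsilon - 1) / epsilon)

        t_eval = np.linspace(0, 5, 101)
        sol = solve_ivp(rhs, (0, 5), [1.0], t_eval=t_eval,
                        rtol=1e-10, atol=1e-12)
        gomp = evaluate_trajectory(
            GrowthModelSpec("gompertz"), [c, d], 1.0, t_eval
        ).values
        assert np.max(np.abs(sol.y[0] - gomp) / gomp) < tol

    def test_limit_domain_errors(self):
        with pytest.raises(ValueError):
            gompertz_limit_approximation(1.0, 0.0, 1.0, 0.2)
        with pytest.raises(ValueError):
            gompertz_limit_approximation(1.0, 1e-3, 0.2, 1.0)  # a <= b


class TestGeneralRhs:
    @pytest.mark.parametrize("N,a,b,g,d,expected", [
        (5.0, 2.0, 0.0, 1.0, 2.0, 10.0),       # exponential specialization
        (10.0, 1.0, 0.1, 1.0, 2.0, 0.0),        # logistic at K = a/b = 10
        (1.0, 1.0, 1.0, 2 / 3, 1.0, 0.0),       # von Bertalanffy at capacity
    ])
    def test_specializations(self, N, a, b, g, d, expected):
        assert general_rhs(N, a, b, g, d) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            general_rhs(-1.0, 1.0, 0.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            general_rhs(1.0, 1.0, 0.0, 1.0, 1.0)  # gamma >= delta


class TestCarryingCapacity:
    def test_printed_formulas(self):
        assert carrying_capacity(GrowthModelSpec("gompertz"), [2.0, 1.0], 1.0) \
            == pytest.approx(math.e**2)
        assert carrying_capacity(
            GrowthModelSpec("von_bertalanffy", 0.5), [4.0, 2.0]
        ) == pytest.approx(4.0)

    def test_cap_at_1e10(self):
        assert carrying_capacity(GrowthModelSpec("gompertz"), [30.0, 1e-4]) == 1e10

    def test_unbounded_families(self):
        assert carrying_capacity(GrowthModelSpec("exponential"), [1.0]) == math.inf
        assert carrying_capacity(GrowthModelSpec("power_law", 0.5), [1.0]) == math.inf
        assert carrying_capacity(GrowthModelSpec("gompertz"), [1.0, 0.0]) == math.inf

    def test_alt_parametrization_matches(self):
        a, b = 1.3, 0.4
        alpha, K = gompertz_alt_parameters(a, b)
        assert alpha == b
        assert K == pytest.approx(carrying_capacity(GrowthModelSpec("gompertz"), [a, b]))
        t = np.linspace(0, 20, 50)
        direct = evaluate_trajectory(GrowthModelSpec("gompertz"), [a, b], 1.0, t)
        alt = evaluate_trajectory(GrowthModelSpec("gompertz_alt"), [alpha, K], 1.0, t)
        np.testing.assert_allclose(direct.values, alt.values, rtol=1e-12)


class TestRatesAndDoubling:
    def test_growth_rate_examples(self):
        assert growth_rate_at(1.0, 0.1, 0.0) == 1.0
        assert growth_rate_at(1.0, 0.1, math.log(2) / 0.1) == pytest.approx(0.5)
        assert growth_rate_at(1.0, 0.0, 123.0) == 1.0

    def test_exponential_limit_both_methods(self):
        for method in ("exact", "instantaneous"):
            assert doubling_time(math.log(2), 0.0, 0.0, method) == pytest.approx(1.0)

    def test_exact_doubling_matches_root_solve(self):
        a, b = math.log(2), 0.1
        d = doubling_time(a, b, 0.0, "exact")
        # independent oracle: root of N(t) = 2 on the Gompertz closed form
        spec = GrowthModelSpec("gompertz")
        d_oracle = brentq(
            lambda t: evaluate_trajectory(spec, [a, b], 1.0, [t]).values[0] - 2.0,
            1e-6, 50.0,
        )
        assert d == pytest.approx(d_oracle, abs=1e-9)
        assert d == pytest.approx(1.0536, abs=1e-4)

    def test_never_doubles_when_capacity_below_two(self):
        # K = e^(a/b) = e^0.5 < 2: the trajectory saturates before doubling
        assert doubling_time(0.05, 0.1, 0.0, "exact") == math.inf
        # K = e^(a/b) = e > 2: doubling occurs, late
        assert doubling_time(0.1, 0.1, 0.0, "exact") == pytest.approx(
            -10.0 * math.log(1.0 - math.log(2)), rel=1e-12
        )
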
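"""Fitness functions: closed forms, reductions between layers, concavity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from lagopt import (
    DiscretizedLagDistribution,
    QFamilySpec,
    effective_bin_weights,
    erlang_lag_pdf,
    fitness_discretized,
    fitness_functional,
    fitness_single_distributed_t,
    fitness_single_fixed_t,
    fitness_two_phenotype,
    growth_factor_general,
    h_coefficient,
    h_matrix,
    log_growth_factor_exp,
    make_duration_distribution,
)

LN_HALF = math.log(0.5)


class TestSinglePhenotypeFixedT:
    def test_no_antibiotic_only_lag_cost(self):
        for T in (0.0, 3.0, 10.0):
            fv = fitness_single_fixed_t(1.0, 1.0, 0.0, T)
            assert fv.total == pytest.approx(LN_HALF, abs=1e-14)
            assert fv.antibiotic_term == 0.0

    def test_zero_lag_boundary_limit(self):
        # instant wake-up: killed at rate γ for all of T, then grows
        fv = fitness_single_fixed_t(0.0, 1.0, 1.0, 6.0)
        assert fv.total == pytest.approx(-12.0, abs=1e-14)

    def test_composition_of_closed_forms(self):
        fv = fitness_single_fixed_t(1.0, 1.0, 0.5, 6.0)
        assert fv.total == pytest.approx(0.5 * LN_HALF + 0.5 * (-12 + math.log(6.5)), abs=1e-12)

    def test_total_splits_into_terms(self):
        fv = fitness_single_fixed_t(2.0, 0.7, 0.3, 4.0)
        assert fv.total == pytest.approx(fv.no_antibiotic_term + fv.antibiotic_term)

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            fitness_single_fixed_t(1.0, 1.0, 1.5, 6.0)

    @given(
        lam=st.floats(0.0, 20.0),
        gamma=st.floats(0.0, 5.0),
        p=st.floats(0.0, 1.0),
        T=st.floats(0.0, 15.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_never_positive(self, lam, gamma, p, T):
        # growth never beats the zero-lag, antibiotic-free baseline
        assert fitness_single_fixed_t(lam, gamma, p, T).total <= 1e-12

    def test_monotone_in_severeness(self):
        base = fitness_single_fixed_t(1.5, 1.0, 0.5, 5.0).total
        assert fitness_single_fixed_t(1.5, 1.0, 0.6, 5.0).total <= base
        assert fitness_single_fixed_t(1.5, 1.5, 0.5, 5.0).total <= base
        assert fitness_single_fixed_t(1.5, 1.0, 0.5, 6.0).total <= base


class TestSinglePhenotypeDistributedT:
    def test_degenerate_distribution_equals_fixed(self):
        q = make_duration_distribution(QFamilySpec("delta", 10.0, 0.1, {"T0": 5.0}))
        for lam in (0.0, 1.0, 3.0):
            assert fitness_single_distributed_t(lam, 1.0, 0.7, q).total == pytest.approx(
                fitness_single_fixed_t(lam, 1.0, 0.7, 5.0).total, abs=1e-12
            )

    def test_p_zero_ignores_duration_law(self):
        q = make_duration_distribution(QFamilySpec("uniform", 4.0, 0.1, {"a": 4.0}))
        assert fitness_single_distributed_t(2.0, 1.0, 0.0, q).total == pytest.approx(
            -math.log(3.0), abs=1e-12
        )

    def test_uniform_duration_matches_quadrature_oracle(self):
        # (1/a) ∫_0^a ln f(T) dT by quadrature vs the binned duration average
        lam, gamma, p, a = 1.0, 1.0, 1.0, 2.0
        oracle, _ = integrate.quad(
            lambda T: log_growth_factor_exp(lam, gamma, T) / a, 0.0, a
        )
        q = make_duration_distribution(QFamilySpec("uniform", a, 2e-5, {"a": a}))
        got = fitness_single_distributed_t(lam, gamma, p, q).total
        assert got == pytest.approx(oracle, abs=1e-4)


class TestTwoPhenotype:
    @pytest.mark.parametrize("x,lam_ref", [(0.0, 0.8), (1.0, 5.0)])
    def test_pure_fractions_reduce_to_single(self, x, lam_ref):
        lam_a, lam_b = (lam_ref, 5.0) if x == 0.0 else (0.8, lam_ref)
        got = fitness_two_phenotype(x, lam_a, lam_b, 1.0, 0.6, 6.0).total
        assert got == pytest.approx(
            fitness_single_fixed_t(lam_ref, 1.0, 0.6, 6.0).total, abs=1e-12
        )

    def test_zero_lag_component_composition(self):
        # one instant-wake phenotype plus one slow: mixture of the boundary
        # growth factor e^{-(1+γ)T} and the closed form
        x, lam_b, gamma, p, T = 0.5, 6.0, 1.0, 0.8, 6.0
        fb_T = math.exp(log_growth_factor_exp(lam_b, gamma, T))
        expected = p * math.log((math.exp(-(1 + gamma) * T) + fb_T) / 2) + (1 - p) * math.log(
            (1 + 1 / (1 + lam_b)) / 2
        )
        got = fitness_two_phenotype(x, 0.0, lam_b, gamma, p, T).total
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_mixed_ode_oracle(self):
        # the population is linear, so the mixture growth factor is the
        # mass-weighted mixture of per-phenotype ODE solutions
        from lagopt import Phenotype, integrate_single_round

        x, la, lb, gamma, p, T = 0.3, 0.5, 6.0, 1.0, 0.8, 6.0
        fa = math.exp(integrate_single_round(Phenotype(la), gamma, T, t_end=60.0).log_rel_growth)
        fb = math.exp(integrate_single_round(Phenotype(lb), gamma, T, t_end=100.0).log_rel_growth)
        fa0 = 1 / (1 + la)
        fb0 = 1 / (1 + lb)
        expected = p * math.log((1 - x) * fa + x * fb) + (1 - p) * math.log(
            (1 - x) * fa0 + x * fb0
        )
        got = fitness_two_phenotype(x, la, lb, gamma, p, T).total
        assert got == pytest.approx(expected, abs=1e-7)

    def test_rejects_invalid_fraction(self):
        with pytest.raises(ValueError):
            fitness_two_phenotype(1.2, 0.0, 1.0, 1.0, 0.5, 6.0)


class TestGrowthFactorGeneral:
    def test_laplace_transform_at_no_antibiotic(self):
        # T = 0: ln ∫ e^{-l} r(l) dl; exponential r gives 1/(1+λ)
        lam = 2.0
        got = growth_factor_general(lambda l: np.exp(-l / lam) / lam, 1.0, 0.0)
        assert got == pytest.approx(math.log(1 / (1 + lam)), abs=1e-9)

    def test_reduces_to_closed_form_for_exponential_lag(self):
        got = growth_factor_general(lambda l: np.exp(-l), 1.0, 6.0)
        assert got == pytest.approx(log_growth_factor_exp(1.0, 1.0, 6.0), abs=1e-9)

    def test_point_mass_after_antibiotic_is_pure_delay(self):
        # all mass in one bin beyond T: ln f = -l0
        n0, delta = 80, 0.1
        w = np.zeros(100)
        w[n0] = 1.0
        r = DiscretizedLagDistribution(delta=delta, weights=w)
        assert growth_factor_general(r, 1.0, 5.0) == pytest.approx(-n0 * delta, abs=1e-12)


class TestFitnessFunctional:
    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("gamma", [0.5, 1.0])
    @pytest.mark.parametrize("p,T0", [(0.3, 2.0), (0.8, 5.0)])
    def test_reduction_chain_to_fixed_t(self, lam, gamma, p, T0):
        # exponential r + delta q collapse the general functional to the
        # single-phenotype fixed-T fitness
        q = make_duration_distribution(QFamilySpec("delta", 10.0, 0.1, {"T0": T0}))
        got = fitness_functional(lambda l: np.exp(-l / lam) / lam, q, gamma, p).total
        expected = fitness_single_fixed_t(lam, gamma, p, T0).total
        assert got == pytest.approx(expected, abs=1e-8)

    def test_p_zero_is_laplace_transform(self):
        q = make_duration_distribution(QFamilySpec("uniform", 4.0, 0.1, {"a": 4.0}))
        got = fitness_functional(lambda l: np.exp(-l / 2) / 2, q, 1.0, 0.0).total
        assert got == pytest.approx(math.log(1 / 3), abs=1e-9)

    def test_converges_to_fine_discretization(self):
        # the continuum quadrature route and F_d agree up to the O(Δ)
        # left-endpoint binning bias, which halves when Δ halves
        from lagopt import discretize_lag_distribution

        t_max = 10.0
        density = lambda l: erlang_lag_pdf(l, 3, 2.0)
        diffs = []
        for delta in (0.02, 0.01):
            q = make_duration_distribution(
                QFamilySpec("normal", t_max, delta, {"mu": 5.0, "sigma": 1.5})
            )
            functional = fitness_functional(density, q, 1.0, 0.8).total
            r = discretize_lag_distribution(density, delta, len(q))
            discretized = fitness_discretized(r.weights, q.weights, 1.0, 0.8, delta).total
            diffs.append(abs(functional - discretized))
        assert diffs[1] < 2.5e-3
        assert 0.3 < diffs[1] / diffs[0] < 0.7


class TestFitnessDiscretized:
    def test_all_mass_at_origin(self):
        n = 50
        r = np.zeros(n)
        r[0] = 1.0
        q = make_duration_distribution(QFamilySpec("uniform", 5.0, 0.1, {"a": 5.0}))
        gamma, p = 1.0, 0.6
        got = fitness_discretized(r, q.weights, gamma, p, 0.1).total
        expected = p * float(q.weights @ (-(1 + gamma) * q.duration_grid))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_first_order_convergence_to_closed_form(self):
        # left-endpoint binning converges O(Δ): Richardson ratio ~ 1/2
        from lagopt import ErlangMixture, discretize_lag_distribution

        lam, gamma, p, T0, t_max = 1.0, 1.0, 0.8, 5.0, 10.0
        exact = fitness_single_fixed_t(lam, gamma, p, T0).total
        errs = []
        for delta in (0.1, 0.05, 0.025):
            n = int(round(t_max / delta))
            q = make_duration_distribution(QFamilySpec("delta", t_max, delta, {"T0": T0}))
            mix = ErlangMixture(fractions=[1.0], lams=[lam], m=1)
            r = discretize_lag_distribution(mix, delta, n)
            errs.append(abs(fitness_discretized(r.weights, q.weights, gamma, p, delta).total - exact))
        assert errs[0] > errs[1] > errs[2]
        for e_coarse, e_fine in zip(errs, errs[1:]):
            assert 0.3 < e_fine / e_coarse < 0.7

    def test_concave_on_simplex(self, rng):
        n = 40
        q = make_duration_distribution(QFamilySpec("uniform", 4.0, 0.1, {"a": 4.0}))
        H = h_matrix(n, 1.0, 0.1)
        for _ in range(100):
            r1 = rng.dirichlet(np.ones(n))
            r2 = rng.dirichlet(np.ones(n))
            mid = 0.5 * (r1 + r2)
            f_mid = fitness_discretized(mid, q.weights, 1.0, 0.7, 0.1, _H=H).total
            f_avg = 0.5 * (
                fitness_discretized(r1, q.weights, 1.0, 0.7, 0.1, _H=H).total
                + fitness_discretized(r2, q.weights, 1.0, 0.7, 0.1, _H=H).total
            )
            assert f_mid >= f_avg - 1e-12

    def test_rejects_mismatched_or_invalid_weights(self):
        q = make_duration_distribution(QFamilySpec("uniform", 4.0, 0.1, {"a": 4.0}))
        with pytest.raises(ValueError):
            fitness_discretized(np.full(10, 0.1), q.weights, 1.0, 0.5, 0.1)
        bad = np.full(len(q), 1.0 / len(q))
        bad[0] += 1e-3
        with pytest.raises(ValueError):
            fitness_discretized(bad, q.weights, 1.0, 0.5, 0.1)


class TestHCoefficients:
    def test_values(self):
        assert h_coefficient(0, 0, 1.0, 0.1) == pytest.approx(1.0)
        assert h_coefficient(0, 2, 1.0, 0.1) == pytest.approx(math.exp(-0.4), rel=1e-12)
        assert h_coefficient(3, 1, 1.0, 0.1) == pytest.approx(math.exp(-0.3), rel=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        H = h_matrix(60, 2.0, 0.1)
        assert np.all(H > 0) and np.all(H <= 1.0)

    def test_average_h_equals_fd_log_arguments(self, rng):
        # <h^m> over r is exactly the argument of the m-th logarithm of F_d
        n, gamma, delta = 30, 1.5, 0.1
        r = rng.dirichlet(np.ones(n))
        H = h_matrix(n, gamma, delta)
        hm = r @ H
        l = np.arange(n) * delta
        for m in range(0, n, 7):
            T = m * delta
            direct = np.exp(-(1 + gamma) * T) * np.sum(
                np.exp(gamma * l[:m]) * r[:m]
            ) + np.sum(np.exp(-l[m:]) * r[m:])
            assert hm[m] == pytest.approx(direct, rel=1e-12)

    def test_effective_weights_sum_to_one(self):
        q = make_duration_distribution(QFamilySpec("exponential", 10.0, 0.1, {"mean": 5.0}))
        w = effective_bin_weights(q.weights, 0.8)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[0] >= 1 - 0.8
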
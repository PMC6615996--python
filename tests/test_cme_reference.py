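"""Truncated master-equation oracle: structure, integration, analytic limits."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist
from scipy.stats import poisson

from snapmix.cme_reference import (
    beta_poisson_pmf,
    build_truncated_generator,
    default_truncation,
    integrate_cme,
    joint_from_cme,
    stationary_initial_condition,
)
from snapmix.model_space import GeneTopology, ParameterSet
from snapmix.pmpdmsr import total_variation


@pytest.fixture(scope="module")
def birth_death():
    topo = GeneTopology(n_states=1, n_alleles=1)
    params = ParameterSet(topo, {"beta_0": 20.0, "delta": 1.0})
    return topo, params


class TestGeneratorStructure:
    def test_single_state_birth_death_chain(self, birth_death):
        topo, params = birth_death
        cme = build_truncated_generator(params, topo, "U", 5)
        A = cme.generator.toarray()
        # births beta, deaths delta*m on the sub/super diagonals
        for m in range(5):
            assert A[m + 1, m] == pytest.approx(20.0)
            assert A[m, m + 1] == pytest.approx(m + 1.0)

    def test_column_sums_vanish_except_boundary_leak(self, birth_death):
        topo, params = birth_death
        M = 6
        cme = build_truncated_generator(params, topo, "U", M)
        cols = np.asarray(cme.generator.sum(axis=0)).ravel()
        np.testing.assert_allclose(cols[:M], 0.0, atol=1e-12)
        assert cols[M] == pytest.approx(-20.0)  # synthesis flux leaving the box

    def test_two_state_generator_matches_hand_enumeration(self):
        """Every entry of a small 2-state single-allele CME vs explicit reactions."""
        topo = GeneTopology(n_states=2, n_alleles=1)
        k01, k10, b0, b1, d = 1.5, 0.7, 2.0, 9.0, 1.3
        params = ParameterSet.from_sequence(topo, (k01, k10, b0, b1, d))
        M = 3
        cme = build_truncated_generator(params, topo, "U", M)
        dim = 2 * (M + 1)
        ref = np.zeros((dim, dim))
        beta = [b0, b1]
        for s in range(2):
            for m in range(M + 1):
                i = s * (M + 1) + m
                j_switch = (1 - s) * (M + 1) + m
                rate = k01 if s == 0 else k10
                ref[j_switch, i] += rate
                ref[i, i] -= rate
                ref[i, i] -= beta[s]  # synthesis leaves (leak at m = M)
                if m < M:
                    ref[i + 1, i] += beta[s]
                if m > 0:
                    ref[i - 1, i] += d * m
                    ref[i, i] -= d * m
        np.testing.assert_allclose(cme.generator.toarray(), ref, atol=1e-12)

    def test_dimension_scales_as_s_squared_m(self, bench_params, topo3):
        cme = build_truncated_generator(bench_params, topo3, "U", 50)
        assert cme.dimension == 9 * 51


class TestIntegration:
    def test_time_zero_returns_p0(self, birth_death):
        topo, params = birth_death
        cme = build_truncated_generator(params, topo, "U", 40)
        p0 = stationary_initial_condition(cme)
        sol = integrate_cme(cme, p0, [0.0, 1.0])
        np.testing.assert_allclose(sol.P[0], p0)

    def test_constitutive_limit_is_poisson(self, birth_death):
        topo, params = birth_death
        M = default_truncation(params, topo)
        cme = build_truncated_generator(params, topo, "U", M)
        p0 = stationary_initial_condition(cme)
        sol = integrate_cme(cme, p0, [0.0, 25.0])
        ref = poisson.pmf(np.arange(M + 1), 20.0)
        assert total_variation(sol.P[1], ref) < 1e-6
        assert sol.mass[1] > 1 - 1e-6

    def test_telegraph_stationary_matches_beta_poisson(self, telegraph_params):
        topo, params = telegraph_params
        M = default_truncation(params, topo)
        cme = build_truncated_generator(params, topo, "U", M)
        p0 = stationary_initial_condition(cme)
        sol = integrate_cme(cme, p0, [0.0, 40.0], rtol=1e-10)
        marg = sol.P[1].reshape(2, M + 1).sum(axis=0)
        ref = beta_poisson_pmf(np.arange(M + 1), 1.0, 2.0, 60.0, 1.0)
        assert total_variation(marg, ref) < 1e-5

    def test_invalid_p0_rejected(self, birth_death):
        topo, params = birth_death
        cme = build_truncated_generator(params, topo, "U", 10)
        with pytest.raises(ValueError):
            integrate_cme(cme, np.ones(cme.dimension), [0.0, 1.0])


class TestBetaPoisson:
    def test_closed_form_matches_quadrature(self):
        """Hypergeometric formula vs direct Beta-mixture integration."""
        a, b, lam = 1.0, 2.0, 60.0
        for m in (0, 3, 20, 60, 110):
            num, _ = quad(
                lambda x: poisson.pmf(m, lam * x) * beta_dist.pdf(x, a, b), 0, 1
            )
            assert beta_poisson_pmf(m, a, b, lam, 1.0) == pytest.approx(num, rel=1e-8)

    def test_normalized(self):
        p = beta_poisson_pmf(np.arange(200), 0.3, 1.7, 45.0, 1.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)


class TestJointFromCme:
    def test_marginalization_preserves_mass(self, bench_params, topo3):
        cme = build_truncated_generator(bench_params, topo3, "U", 80)
        p0 = stationary_initial_condition(cme)
        sol = integrate_cme(cme, p0, [0.0, 0.5])
        joint = joint_from_cme(sol, {1, 2})
        for l in range(2):
            assert joint.probs[l].sum() == pytest.approx(sol.P[l].sum(), abs=1e-12)

    def test_empty_active_set_puts_mass_at_ts_zero(self, birth_death):
        topo, params = birth_death
        cme = build_truncated_generator(params, topo, "U", 30)
        sol = integrate_cme(cme, stationary_initial_condition(cme), [0.0, 2.0])
        joint = joint_from_cme(sol, set())
        assert joint.probs[1, :, 0].sum() == pytest.approx(sol.P[1].sum())


class TestCrossValidation:
    def test_hybrid_matches_cme_single_allele_benchmark(self, topo3_single):
        """Induction transient: Poisson-mixture engine vs master equation."""
        from snapmix.pmpdmsr import build_mixture, mixture_to_joint

        params = ParameterSet.from_sequence(
            topo3_single,
            (0.5, 0.5, 5, 5, 20, 150, 300, 1),
            {"kappa_21": 0.5, "kappa_10": 0.5},
        )
        times = [9.9, 12.0]
        n_s = 20_000
        kernel = build_mixture(params, topo3_single, times, n_s, induction_time=10, seed=4)
        joint = mixture_to_joint(kernel, {1, 2})
        M = default_truncation(params, topo3_single)
        cme_u = build_truncated_generator(params, topo3_single, "U", M)
        cme_s = build_truncated_generator(params, topo3_single, "S", M)
        sol = integrate_cme(
            (cme_u, cme_s),
            stationary_initial_condition(cme_u),
            times,
            induction_time=10.0,
            t0=-10.0,
        )
        ref = joint_from_cme(sol, {1, 2})
        for l in range(len(times)):
            assert (
                total_variation(joint.probs[l], ref.probs[l])
                < 3.0 / np.sqrt(n_s) + 0.01
            )
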
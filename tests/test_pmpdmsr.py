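"""Hybrid simulator: path sampling, rate propagation, and the Poisson mixture."""

import numpy as np
import pytest
from scipy.stats import poisson

from snapmix.model_space import GeneTopology, ParameterSet, build_generator
from snapmix.pmpdmsr import (
    MixtureKernel,
    build_mixture,
    default_active_set,
    mixture_pmf_at,
    mixture_to_joint,
    propagate_lambda,
    sample_genetic_path,
    stationary_state_distribution,
    total_variation,
    ts_count,
)


class TestStationaryDistribution:
    def test_symmetric_two_state(self):
        Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        np.testing.assert_allclose(stationary_state_distribution(Q), [0.5, 0.5])

    def test_benchmark_generator_null_space(self, bench_params, topo3):
        Q = build_generator(bench_params, topo3, "U")
        pi = stationary_state_distribution(Q)
        assert np.max(np.abs(pi @ Q)) < 1e-12
        assert pi.sum() == pytest.approx(1.0)
        assert np.all(pi > 0)

    def test_matches_long_run_occupancy(self, bench_params, topo3):
        """Null-space solution vs empirical KMC occupancy at a late time."""
        Q = build_generator(bench_params, topo3, "U")
        pi = stationary_state_distribution(Q)
        kernel = build_mixture(
            bench_params, topo3, [0.0], 20_000, induction_time=1e9, seed=5
        )
        occ = np.bincount(kernel.states[:, :, 0].ravel(), minlength=3) / 40_000
        np.testing.assert_allclose(occ, pi, atol=0.01)

    def test_reducible_generator_rejected(self):
        Q = np.array([[-1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            stationary_state_distribution(Q)


class TestPropagateLambda:
    def test_fixed_point(self):
        assert propagate_lambda(0.0, 20.0, 1.0, 1e3) == pytest.approx(20.0)

    def test_half_rise(self):
        assert propagate_lambda(0.0, 20.0, 1.0, np.log(2)) == pytest.approx(10.0)

    def test_pure_decay_halves(self):
        assert propagate_lambda(8.0, 0.0, 1.0, np.log(2)) == pytest.approx(4.0)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            propagate_lambda(1.0, 1.0, 1.0, -0.1)


class TestGeneticPath:
    def test_frozen_chain_stays_constant(self):
        topo = GeneTopology(n_states=3, n_alleles=1)
        params = ParameterSet.from_sequence(topo, (0, 0, 0, 0, 1.0, 2.0, 3.0, 1.0))
        path = sample_genetic_path(
            params, topo, (0.0, 50.0), 25.0, np.random.default_rng(0)
        )
        assert len(path.states) == 1

    def test_switch_count_mean_matches_rate(self):
        """Symmetric 2-state chain: switches in T have mean ~ 2 * r * T / 2."""
        topo = GeneTopology(n_states=2, n_alleles=1)
        r, T = 0.8, 20.0
        params = ParameterSet.from_sequence(topo, (r, r, 0.0, 1.0, 1.0))
        rng = np.random.default_rng(1)
        counts = [
            len(sample_genetic_path(params, topo, (0.0, T), 1e9, rng).switch_times) - 1
            for _ in range(400)
        ]
        # at equilibrium each direction fires at rate r/2; total r*T
        assert np.mean(counts) == pytest.approx(r * T, rel=0.1)

    def test_lambda_along_path_matches_piecewise_formula(self, topo3_single):
        params = ParameterSet.from_sequence(
            topo3_single, (0.5, 0.5, 5, 5, 20, 150, 300, 1)
        )
        path = sample_genetic_path(
            params, topo3_single, (0.0, 10.0), 1e9, np.random.default_rng(2)
        )
        lam = path.lambda_at(params, [10.0])[0]
        # manual piecewise propagation
        cuts = list(path.switch_times) + [10.0]
        lam_ref, t_cur = 0.0, 0.0
        for k in range(len(path.states)):
            dt = cuts[k + 1] - cuts[k]
            beta = params.value(f"beta_{path.states[k]}", "U")
            lam_ref = propagate_lambda(lam_ref, beta, 1.0, dt)
        assert lam == pytest.approx(lam_ref, rel=1e-12)


class TestTsCount:
    @pytest.mark.parametrize(
        "states,expected", [((0, 0), 0), ((1, 2), 2), ((0, 2), 1)]
    )
    def test_examples(self, states, expected):
        assert ts_count(np.array(states), {1, 2}) == expected

    def test_default_active_set_excludes_basal(self, topo3):
        assert default_active_set(topo3) == frozenset({1, 2})


class TestMixture:
    def test_silent_gene_has_zero_rate(self):
        topo = GeneTopology(n_states=1, n_alleles=1)
        params = ParameterSet(topo, {"beta_0": 0.0, "delta": 1.0})
        kernel = build_mixture(params, topo, [1.0, 5.0], 1, seed=0)
        assert np.all(kernel.lam == 0.0)
        joint = mixture_to_joint(kernel, set())
        assert joint.probs[0, 0, 0] == pytest.approx(1.0)

    def test_unit_rate_point_mass(self):
        kernel = MixtureKernel(
            np.array([0.0]),
            np.zeros((1, 2, 1), dtype=np.int64),
            np.array([[[0.4], [0.6]]]),
        )
        joint = mixture_to_joint(kernel, {1}, m_support=30)
        # both alleles inactive -> TS = 0; total rate 1.0
        assert joint.probs[0, 0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_total_rate_adds_over_alleles(self, bench_params, topo3):
        kernel = build_mixture(bench_params, topo3, [2.0], 50, induction_time=1.0, seed=3)
        np.testing.assert_allclose(
            kernel.lam_total(0), kernel.lam[:, :, 0].sum(axis=1)
        )

    def test_same_seed_bit_identical(self, bench_params, topo3):
        k1 = build_mixture(bench_params, topo3, [9.9, 16.0], 500, induction_time=10, seed=7)
        k2 = build_mixture(bench_params, topo3, [9.9, 16.0], 500, induction_time=10, seed=7)
        assert np.array_equal(k1.lam, k2.lam)
        assert np.array_equal(k1.states, k2.states)
        k3 = build_mixture(bench_params, topo3, [9.9, 16.0], 500, induction_time=10, seed=8)
        assert not np.array_equal(k3.lam, k1.lam)

    def test_observation_outside_window_rejected(self, bench_params, topo3):
        with pytest.raises(ValueError):
            build_mixture(bench_params, topo3, [-20.0, 5.0], 10, burn_in=10.0, seed=0)

    def test_constant_state_converges_to_poisson(self, constitutive_params):
        """After t >> 1/delta the constitutive gene is Poisson(beta/delta)."""
        topo, params = constitutive_params
        kernel = build_mixture(params, topo, [5.0], 200, induction_time=1e9, seed=0)
        joint = mixture_to_joint(kernel, set())
        ref = poisson.pmf(np.arange(joint.m_max + 1), 20.0)
        assert total_variation(joint.probs[0, :, 0], ref) < 1e-6

    def test_monte_carlo_convergence_rate(self, telegraph_params):
        """TV to the stationary law decays roughly like N_s^(-1/2)."""
        from snapmix.cme_reference import beta_poisson_pmf

        topo, params = telegraph_params
        ref = beta_poisson_pmf(np.arange(161), 1.0, 2.0, 60.0, 1.0)
        tvs = {}
        for n in (100, 10_000):
            kernel = build_mixture(params, topo, [0.0], n, induction_time=1e9, seed=11)
            joint = mixture_to_joint(kernel, {1}, m_support=160)
            tvs[n] = total_variation(joint.probs[0].sum(axis=1), ref)
        assert tvs[10_000] < 0.5 * tvs[100]
        assert tvs[10_000] < 3.0 / np.sqrt(10_000) + 0.01


class TestPmfAt:
    def test_consistent_with_full_joint(self, bench_params, topo3):
        kernel = build_mixture(
            bench_params, topo3, [9.9, 13.0], 2000, induction_time=10.0, seed=1
        )
        active = default_active_set(topo3)
        joint = mixture_to_joint(kernel, active)
        bins = [(0, 0), (5, 1), (40, 2), (300, 1), (700, 2)]
        for l in range(2):
            probs = mixture_pmf_at(kernel, bins, l, active)
            for (m, ts), p in zip(bins, probs):
                assert p == pytest.approx(joint.probs[l, m, ts], abs=1e-12)

    def test_deep_tail_is_negligible(self, constitutive_params):
        topo, params = constitutive_params
        kernel = build_mixture(params, topo, [5.0], 100, induction_time=1e9, seed=0)
        (p,) = mixture_pmf_at(kernel, [(200, 0)], 0, set())
        assert p < 1e-10

    def test_empty_bin_list(self, constitutive_params):
        topo, params = constitutive_params
        kernel = build_mixture(params, topo, [5.0], 10, induction_time=1e9, seed=0)
        assert mixture_pmf_at(kernel, [], 0, set()).size == 0


class TestJointDistribution:
    def test_mass_accounting(self, bench_params, topo3):
        kernel = build_mixture(bench_params, topo3, [9.9], 2000, induction_time=10, seed=2)
        joint = mixture_to_joint(kernel, default_active_set(topo3))
        assert joint.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(joint.tail_mass < 1e-9)

    def test_tsv_round_trip(self, tmp_path, bench_params, topo3):
        kernel = build_mixture(bench_params, topo3, [9.9], 500, induction_time=10, seed=2)
        joint = mixture_to_joint(kernel, default_active_set(topo3))
        out = tmp_path / "joint.tsv"
        joint.to_tsv(out, metadata={"seed": 2})
        import pandas as pd

        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == ["time", "m", "TS", "probability"]
        assert df["probability"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (tmp_path / "joint.tsv.json").exists()
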
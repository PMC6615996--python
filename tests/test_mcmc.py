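"""Metropolis-Hastings machinery: priors, proposals, chains."""

import numpy as np
import pytest
from scipy.integrate import dblquad, quad
from scipy.stats import kstest

from snapmix.mcmc import (
    MHState,
    ParameterVector,
    PriorSpec,
    ProposalSpec,
    log_prior,
    mh_step,
    propose,
    run_chain,
)
from snapmix.model_space import ParameterSet, parse_code
from tests.conftest import BENCHMARK_STIMULATED, BENCHMARK_RATES


class FlatEngine:
    """Constant likelihood: the posterior is the prior."""

    def log_likelihood(self, params, seed, n_paths=None):
        return 0.0, 0


class StepEngine:
    """1-D two-level likelihood: L = hi for theta < 1, lo otherwise."""

    def __init__(self, log_hi, log_lo):
        self.log_hi, self.log_lo = log_hi, log_lo

    def __call__(self, theta):
        return self.log_hi if theta[0] < 1.0 else self.log_lo


class TestLogPrior:
    def test_closed_form_at_lower_bound(self):
        prior = PriorSpec([1.0], [np.e])
        assert log_prior([1.0], prior) == pytest.approx(0.0)

    def test_outside_support(self):
        prior = PriorSpec([1.0], [10.0])
        assert log_prior([0.5], prior) == -np.inf
        assert log_prior([20.0], prior) == -np.inf

    def test_normalization_1d(self):
        prior = PriorSpec([0.1], [50.0])
        total, _ = quad(lambda t: np.exp(log_prior([t], prior)), 0.1, 50.0)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_normalization_2d(self):
        prior = PriorSpec([0.5, 1.0], [5.0, 100.0])
        total, _ = dblquad(
            lambda y, x: np.exp(log_prior([x, y], prior)),
            0.5, 5.0, 1.0, 100.0,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec([0.0], [1.0])
        with pytest.raises(ValueError):
            PriorSpec([2.0], [1.0])


class TestPropose:
    def test_vanishing_step_is_identity(self):
        rng = np.random.default_rng(0)
        theta = np.array([1.0, 10.0])
        out = propose(theta, ProposalSpec(step_sigma=1e-12), rng)
        np.testing.assert_allclose(out, theta, rtol=1e-9)

    def test_symmetric_in_log_space(self):
        rng = np.random.default_rng(1)
        theta = np.array([3.0])
        draws = np.log([propose(theta, ProposalSpec(0.2), rng)[0] for _ in range(4000)])
        assert np.mean(draws) == pytest.approx(np.log(3.0), abs=0.02)
        assert np.std(draws) == pytest.approx(0.2 * np.log(10), rel=0.1)

    def test_proposals_may_leave_prior_box(self):
        rng = np.random.default_rng(2)
        theta = np.array([1e-2])  # at the default lower bound
        outs = [propose(theta, ProposalSpec(0.5), rng)[0] for _ in range(100)]
        assert min(outs) < 1e-2  # rejected later by the prior, not here


class TestMHStep:
    def _state(self, theta, ll, prior):
        return MHState(np.asarray(theta, float), ll, log_prior(theta, prior))

    def test_uphill_always_accepted(self):
        prior = PriorSpec([0.1], [10.0])
        rng = np.random.default_rng(3)
        state = self._state([1.0], -100.0, prior)
        new, accepted = mh_step(
            state, lambda th: 0.0, prior, ProposalSpec(0.01), rng
        )
        assert accepted and new.log_l == 0.0

    def test_outside_prior_never_accepted(self):
        prior = PriorSpec([0.99], [1.01])
        rng = np.random.default_rng(4)
        state = self._state([1.0], 0.0, prior)
        for _ in range(50):
            new, accepted = mh_step(
                state, lambda th: 1e6, prior, ProposalSpec(1.0), rng
            )
            if accepted:
                assert 0.99 <= new.theta[0] <= 1.01

    def test_two_level_posterior_occupancy_matches_ratio(self):
        """Long-run occupancy of a step-function posterior vs direct integration."""
        prior = PriorSpec([0.1], [10.0])
        engine = StepEngine(np.log(3.0), 0.0)
        rng = np.random.default_rng(5)
        state = self._state([0.5], engine([0.5]), prior)
        prop = ProposalSpec(step_sigma=0.5, adapt_covariance=False)
        hits = 0
        n = 30_000
        for _ in range(n):
            state, _ = mh_step(state, engine, prior, prop, rng)
            hits += state.theta[0] < 1.0
        # posterior mass of {theta < 1} by quadrature of L * prior
        num, _ = quad(lambda t: 3.0 * np.exp(log_prior([t], prior)), 0.1, 1.0)
        den, _ = quad(lambda t: np.exp(log_prior([t], prior)), 1.0, 10.0)
        expected = num / (num + den)
        assert hits / n == pytest.approx(expected, abs=0.02)


class TestParameterVector:
    def test_round_trip_and_ordering(self, topo3):
        params = ParameterSet.from_sequence(
            topo3, BENCHMARK_RATES, BENCHMARK_STIMULATED, {"beta_0": False, "delta": False}
        )
        pv = ParameterVector(parse_code("00110000", topo3), params)
        assert pv.names == [
            "kappa_01", "kappa_12", "kappa_21", "kappa_10", "beta_1", "beta_2",
            "kappa_21_S", "kappa_10_S",
        ]
        theta = pv.from_params(params)
        back = pv.to_params(theta)
        assert back.unstimulated == params.unstimulated
        assert back.stimulated == params.stimulated

    def test_non_induced_theta_drives_both_phases(self, topo3, bench_params):
        pv = ParameterVector(parse_code("00110000", topo3), bench_params)
        theta = pv.from_params(bench_params)
        theta[pv.names.index("kappa_01")] = 2.5
        p = pv.to_params(theta)
        assert p.unstimulated["kappa_01"] == p.stimulated["kappa_01"] == 2.5

    def test_induced_fixed_rejected(self, topo3):
        params = ParameterSet.from_sequence(
            topo3, BENCHMARK_RATES, BENCHMARK_STIMULATED, {"kappa_21": False}
        )
        with pytest.raises(ValueError):
            ParameterVector(parse_code("00110000", topo3), params)


class TestRunChain:
    def test_flat_likelihood_recovers_prior(self, topo3, bench_params):
        """With L constant the chain must sample the log-uniform prior."""
        model = parse_code("00000000", topo3)
        params = ParameterSet.from_sequence(
            topo3, BENCHMARK_RATES, free_mask={n: False for n in topo3.parameter_names()}
            | {"kappa_01": True, "beta_1": True},
        )
        prior = PriorSpec.uniform_box(2, (1e-1, 1e3))
        chain = run_chain(
            None, model, params, prior, ProposalSpec(0.8, adapt_covariance=False),
            FlatEngine(), n_steps=30_000, burn_in=2_000, thinning=10, seed=0,
        )
        for j in range(2):
            u = (np.log10(chain.draws[:, j]) + 1.0) / 4.0  # map box to [0, 1]
            assert kstest(u, "uniform").pvalue > 0.01

    def test_same_seed_identical_chains(self, topo3, bench_params):
        model = parse_code("00110000", topo3)
        kwargs = dict(
            n_steps=500, burn_in=100, thinning=5, seed=3,
        )
        prior = PriorSpec.uniform_box(10)
        a = run_chain(None, model, bench_params, prior, ProposalSpec(), FlatEngine(), **kwargs)
        b = run_chain(None, model, bench_params, prior, ProposalSpec(), FlatEngine(), **kwargs)
        assert np.array_equal(a.draws, b.draws)
        assert a.acceptance_rate == b.acceptance_rate

    def test_draws_stay_inside_prior(self, topo3, bench_params):
        model = parse_code("00000000", topo3)
        prior = PriorSpec.uniform_box(8, (0.5, 2.0))
        params = ParameterSet.from_sequence(topo3, [1.0] * 7 + [1.0])
        chain = run_chain(
            None, model, params, prior, ProposalSpec(0.3), FlatEngine(),
            n_steps=2_000, burn_in=200, thinning=5, seed=1,
        )
        assert np.all(chain.draws >= 0.5) and np.all(chain.draws <= 2.0)

    def test_start_outside_prior_rejected(self, topo3, bench_params):
        model = parse_code("00000000", topo3)
        prior = PriorSpec.uniform_box(8, (1e3, 1e4))  # excludes the start values
        with pytest.raises(ValueError):
            run_chain(
                None, model, bench_params, prior, ProposalSpec(), FlatEngine(),
                n_steps=10, burn_in=0, thinning=1, seed=0,
            )
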
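"""Metropolis-Hastings posterior sampling of kinetic parameters.

The sampled vector theta collects, in canonical parameter order, the free
base (pre-induction) values followed by the post-induction values of the
induced parameters.  Priors are independent log-uniform boxes; proposals
are joint Gaussian steps in log10-parameter space (symmetric, so the
Hastings correction is unity), with the step size adapted toward a target
acceptance rate during burn-in only and frozen afterwards.

The likelihood of a proposal is evaluated by simulating a fresh Poisson
mixture kernel (pseudo-marginal style) or, optionally, by re-simulating
with a common random-number seed so the chain targets one fixed noisy
surface.  On rejection the current state's stored log-likelihood is kept,
as pseudo-marginal correctness requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import SnapshotHistogram, log_likelihood, log_multinomial_coefficient
from .model_space import (
    GeneTopology,
    InductionModel,
    ParameterSet,
    free_parameter_count,
)
from .pmpdmsr import build_mixture, default_active_set, mixture_pmf_at

__all__ = [
    "PriorSpec",
    "ProposalSpec",
    "ParameterVector",
    "SnapshotLikelihoodEngine",
    "PosteriorChain",
    "log_prior",
    "propose",
    "mh_step",
    "run_chain",
]

DEFAULT_PRIOR_BOUNDS = (1e-2, 1e3)


@dataclass
class PriorSpec:
    """Independent log-uniform priors: density 1/(theta_i * ln(u_i/l_i)) on (l_i, u_i)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper shape mismatch")
        if np.any(self.lower <= 0) or np.any(self.upper <= self.lower):
            raise ValueError("need 0 < lower < upper")

    @classmethod
    def uniform_box(cls, dim: int, bounds=DEFAULT_PRIOR_BOUNDS) -> "PriorSpec":
        lo, hi = bounds
        return cls(np.full(dim, lo), np.full(dim, hi))

    @property
    def dim(self) -> int:
        return self.lower.size

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        shape = (self.dim,) if size is None else (size, self.dim)
        u = rng.random(shape)
        return np.exp(np.log(self.lower) + u * (np.log(self.upper) - np.log(self.lower)))

    def log_density_logspace(self) -> float:
        """Constant log-density of the prior in ln(theta) coordinates."""
        return float(-np.log(np.log(self.upper / self.lower)).sum())


def log_prior(theta, prior: PriorSpec) -> float:
    """Log density of the log-uniform prior at theta (-inf outside the box)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.shape != prior.lower.shape:
        raise ValueError("theta dimension does not match prior")
    if np.any(theta < prior.lower) or np.any(theta > prior.upper):
        return -np.inf
    return float(-(np.log(theta) + np.log(np.log(prior.upper / prior.lower))).sum())


@dataclass
class ProposalSpec:
    """Joint Gaussian proposal in log10-parameter space.

    ``step_sigma`` is the per-coordinate standard deviation in decades;
    during burn-in the global scale is adjusted every ``adapt_window`` steps
    toward ``target_acceptance`` and, if ``adapt_covariance`` is set, the
    proposal covariance is replaced by the running empirical covariance of
    the chain (adaptive Metropolis); both are frozen after burn-in so the
    post-burn-in kernel is a fixed, valid MH kernel.
    """

    step_sigma: float = 0.05
    target_acceptance: float = 0.23
    adapt_window: int = 50
    adapt_covariance: bool = True
    cov: np.ndarray | None = None  # optional fixed covariance (decades^2)

    def __post_init__(self):
        if self.step_sigma <= 0:
            raise ValueError("step_sigma must be > 0")


def propose(theta, proposal: ProposalSpec, rng: np.random.Generator) -> np.ndarray:
    """theta' = theta * 10^eps, eps ~ N(0, Sigma) in decades (symmetric).

    Sigma is ``step_sigma^2 * I`` unless ``proposal.cov`` supplies a full
    covariance, in which case ``step_sigma`` acts as a global scale factor.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if proposal.cov is not None:
        eps = proposal.step_sigma * rng.multivariate_normal(
            np.zeros(theta.size), proposal.cov, method="cholesky"
        )
    else:
        eps = rng.normal(0.0, proposal.step_sigma, size=theta.shape)
    return theta * 10.0**eps


class ParameterVector:
    """Bidirectional map between the sampled theta vector and a ParameterSet.

    Coordinates: free base parameters (canonical order, driving both phases
    when not induced), then stimulated-phase values of induced parameters
    (canonical order).
    """

    def __init__(self, model: InductionModel, base: ParameterSet):
        self.model = model
        self.base = base
        self.topology = base.topology
        induced = set(model.induced_parameters)
        names = self.topology.parameter_names()
        for n in induced:
            if not base.free_mask[n]:
                raise ValueError(f"induced parameter {n} cannot be fixed")
        self.base_names = [n for n in names if base.free_mask[n]]
        self.induced_names = [n for n in names if n in induced]
        self.names = self.base_names + [n + "_S" for n in self.induced_names]

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_params(self, theta) -> ParameterSet:
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.dim:
            raise ValueError("theta has wrong dimension")
        u = dict(self.base.unstimulated)
        nb = len(self.base_names)
        for n, v in zip(self.base_names, theta[:nb]):
            u[n] = float(v)
        s = dict(u)
        for n, v in zip(self.induced_names, theta[nb:]):
            s[n] = float(v)
        return ParameterSet(self.topology, u, s, dict(self.base.free_mask))

    def from_params(self, params: ParameterSet) -> np.ndarray:
        vals = [params.unstimulated[n] for n in self.base_names]
        vals += [params.stimulated[n] for n in self.induced_names]
        return np.array(vals)

    def free_count(self) -> int:
        return free_parameter_count(self.model, self.base)


class SnapshotLikelihoodEngine:
    """Evaluates the snapshot log-likelihood of a ParameterSet via the hybrid simulator.

    ``kernel_mode='fresh'`` regenerates an independent mixture kernel per
    call (pseudo-marginal); ``'fixed'`` reuses one common-random-number seed
    so every call sees the same noisy-but-deterministic surface.
    """

    def __init__(
        self,
        histogram: SnapshotHistogram,
        topology: GeneTopology,
        induction_time: float,
        n_paths: int = 10_000,
        burn_in: float | None = None,
        active_set=None,
        kernel_mode: str = "fresh",
        base_seed: int = 0,
        include_multinomial: bool = True,
        floor: float = 1e-12,
    ):
        if kernel_mode not in ("fresh", "fixed"):
            raise ValueError("kernel_mode must be 'fresh' or 'fixed'")
        self.histogram = histogram
        self.topology = topology
        self.induction_time = float(induction_time)
        self.n_paths = int(n_paths)
        self.burn_in = burn_in
        self.active_set = (
            default_active_set(topology) if active_set is None else frozenset(active_set)
        )
        self.kernel_mode = kernel_mode
        self.base_seed = int(base_seed)
        self.include_multinomial = include_multinomial
        self.floor = floor
        self._bins = [
            histogram.bin_arrays(l) for l in range(len(histogram.observation_times))
        ]
        self._log_mult = sum(
            log_multinomial_coefficient(c) for _, _, c in self._bins
        )

    def log_likelihood(self, params: ParameterSet, seed: int, n_paths: int | None = None):
        """Return (total log-likelihood, n_floored) for one parameter set."""
        if self.kernel_mode == "fixed" and n_paths is None:
            seed = self.base_seed  # common random numbers across evaluations
        kernel = build_mixture(
            params,
            self.topology,
            self.histogram.observation_times,
            n_paths or self.n_paths,
            induction_time=self.induction_time,
            burn_in=self.burn_in,
            seed=int(seed),
        )
        probs = []
        for l, (m, ts, _) in enumerate(self._bins):
            probs.append(
                mixture_pmf_at(kernel, list(zip(m, ts)), l, self.active_set)
            )
        val = log_likelihood(
            self.histogram,
            probs,
            include_multinomial=self.include_multinomial,
            floor=self.floor,
        )
        return val.total, val.n_floored


@dataclass
class MHState:
    theta: np.ndarray
    log_l: float
    log_p: float

    @property
    def log_post(self) -> float:
        return self.log_l + self.log_p


def mh_step(
    state: MHState,
    log_likelihood_fn,
    prior: PriorSpec,
    proposal: ProposalSpec,
    rng: np.random.Generator,
) -> tuple[MHState, bool]:
    """One Metropolis-Hastings step; on rejection the state is unchanged.

    ``log_likelihood_fn(theta)`` is only called for proposals inside the
    prior support.  The multiplicative proposal is symmetric in log(theta)
    but not in theta, so the acceptance ratio carries the Jacobian
    (Hastings) factor prod_i theta'_i / theta_i alongside the theta-space
    prior density; for a log-uniform prior the two combine so the chain
    samples uniformly in log(theta) under a flat likelihood, as it must.
    """
    theta_new = propose(state.theta, proposal, rng)
    lp_new = log_prior(theta_new, prior)
    if not np.isfinite(lp_new):
        return state, False
    ll_new = log_likelihood_fn(theta_new)
    log_hastings = float(np.sum(np.log(theta_new) - np.log(state.theta)))
    log_ratio = (ll_new + lp_new) - (state.log_l + state.log_p) + log_hastings
    if np.log(rng.random()) < log_ratio:
        return MHState(theta_new, ll_new, lp_new), True
    return state, False


@dataclass
class PosteriorChain:
    """Thinned post-burn-in draws plus bookkeeping for evidence and criteria."""

    names: list[str]
    draws: np.ndarray  # (T, k)
    log_l: np.ndarray
    log_p: np.ndarray
    acceptance_rate: float
    seed: int
    n_steps: int
    burn_in: int
    thinning: int
    best_theta: np.ndarray = None
    max_log_l: float = -np.inf
    step_sigma_final: float = np.nan
    n_floored_total: int = 0

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def credible_interval(self, name: str, level: float = 0.95):
        j = self.names.index(name)
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.draws[:, j], [a, 1.0 - a])
        return float(lo), float(hi)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.draws, columns=self.names)
        df.insert(0, "logPrior", self.log_p)
        df.insert(0, "logL", self.log_l)
        return df


def _anneal(theta0, ll_fn, prior, rng, n_iter: int, step0: float = 0.4):
    """Simulated-annealing hill climb in log-parameter space.

    A cheap mode-finding initializer for short chains: step size and
    temperature decay geometrically; downhill moves are accepted with
    Boltzmann probability so the search can cross the local roughness of a
    Monte Carlo likelihood surface.
    """
    d = theta0.size
    th = theta0.copy()
    best = th.copy()
    l_cur = ll_fn(th)
    l_best = l_cur
    for i in range(n_iter):
        frac = i / max(n_iter - 1, 1)
        step = step0 * (0.01 / step0) ** frac
        temp = max(20.0 * (1.0 - frac) ** 2, 0.5)
        cand = th * 10.0 ** rng.normal(0.0, step, d)
        cand = np.clip(cand, prior.lower, prior.upper)
        l_cand = ll_fn(cand)
        if l_cand > l_cur or rng.random() < np.exp((l_cand - l_cur) / temp):
            th, l_cur = cand, l_cand
            if l_cur > l_best:
                best, l_best = th.copy(), l_cur
    return best


def run_chain(
    histogram: SnapshotHistogram,
    model: InductionModel,
    params0: ParameterSet,
    prior: PriorSpec,
    proposal: ProposalSpec,
    engine,
    n_steps: int = 1_000_000,
    burn_in: int = 100_000,
    thinning: int = 100,
    seed: int = 0,
    n_init: int = 0,
    n_anneal: int = 0,
    reevaluate_current: bool = False,
) -> PosteriorChain:
    """Metropolis-Hastings chain over the free parameters of one induction model.

    ``engine`` provides ``log_likelihood(params, seed) -> (logL, n_floored)``.
    If ``n_init > 0``, that many prior draws are scored first and the best
    (optionally refined by ``n_anneal`` simulated-annealing iterations)
    becomes the starting point — a mode-finding heuristic for short chains;
    otherwise the chain starts at ``params0``.  During burn-in the proposal
    covariance adapts to the chain history (adaptive Metropolis) and its
    global scale is tuned toward the target acceptance; both freeze at the
    end of burn-in.  Reproducible bit-for-bit for a fixed seed.

    With ``reevaluate_current`` the current state's log-likelihood is
    refreshed with an independent kernel every step (Monte Carlo within
    Metropolis).  Unlike holding a single stored estimate, this cannot lock
    onto a lucky kernel or onto one fixed kernel's bias; the cost is a
    posterior mildly widened by the Monte Carlo noise, which disappears as
    the kernel size grows.
    """
    del histogram  # data enters through the engine; kept for interface clarity
    rng = np.random.default_rng(seed)
    pv = ParameterVector(model, params0)
    if prior.dim == 1 and pv.dim > 1:
        prior = PriorSpec(
            np.full(pv.dim, prior.lower[0]), np.full(pv.dim, prior.upper[0])
        )
    if prior.dim != pv.dim:
        raise ValueError(f"prior dimension {prior.dim} != parameter dimension {pv.dim}")

    n_floored_total = 0

    def _ll(theta) -> float:
        nonlocal n_floored_total
        ll, nf = engine.log_likelihood(
            pv.to_params(theta), int(rng.integers(2**31 - 1))
        )
        n_floored_total += nf
        return ll

    theta0 = pv.from_params(params0)
    if n_init > 0:
        cands = prior.sample(rng, n_init)
        scores = np.array([_ll(c) + log_prior(c, prior) for c in cands])
        theta0 = cands[int(np.argmax(scores))]
    if n_anneal > 0:
        theta0 = _anneal(np.asarray(theta0, float), _ll, prior, rng, n_anneal)
    lp0 = log_prior(theta0, prior)
    if not np.isfinite(lp0):
        raise ValueError("initial parameters outside prior support")
    state = MHState(np.asarray(theta0, dtype=float), _ll(theta0), lp0)

    import warnings

    d = pv.dim
    sigma = proposal.step_sigma
    # running moments of log10(theta) for covariance adaptation
    run_n = 0
    run_mean = np.zeros(d)
    run_m2 = np.zeros((d, d))
    cov_prop = None
    window_acc = 0
    kept_theta, kept_ll, kept_lp = [], [], []
    n_acc_post = 0
    n_post = 0
    best_theta, best_post, max_ll = state.theta.copy(), state.log_post, state.log_l
    for step in range(n_steps):
        prop = ProposalSpec(
            sigma, proposal.target_acceptance, proposal.adapt_window,
            adapt_covariance=False, cov=cov_prop,
        )
        if reevaluate_current:
            state = MHState(state.theta, _ll(state.theta), state.log_p)
        state, accepted = mh_step(state, _ll, prior, prop, rng)
        if accepted:
            window_acc += 1
        if state.log_post > best_post:
            best_post, best_theta = state.log_post, state.theta.copy()
        max_ll = max(max_ll, state.log_l)
        if step < burn_in:
            x = np.log10(state.theta)
            run_n += 1
            delta = x - run_mean
            run_mean += delta / run_n
            run_m2 += np.outer(delta, x - run_mean)
            if (step + 1) % proposal.adapt_window == 0:
                rate = window_acc / proposal.adapt_window
                sigma *= float(np.exp(0.7 * (rate - proposal.target_acceptance)))
                sigma = float(np.clip(sigma, 1e-4, 2.0))
                window_acc = 0
                if proposal.adapt_covariance and run_n > 20 * d:
                    emp = run_m2 / (run_n - 1)
                    emp = emp + 1e-8 * np.eye(d)
                    scale = (2.38**2 / d) / proposal.step_sigma**2
                    cov_prop = scale * emp
        else:
            cov_prop = cov_prop  # frozen
            n_post += 1
            if accepted:
                n_acc_post += 1
            if (step - burn_in) % thinning == 0:
                kept_theta.append(state.theta.copy())
                kept_ll.append(state.log_l)
                kept_lp.append(state.log_p)
    if n_floored_total > 0:
        warnings.warn(
            f"{n_floored_total} observed bins hit the probability floor "
            "during sampling",
            stacklevel=2,
        )
    return PosteriorChain(
        names=pv.names,
        draws=np.array(kept_theta) if kept_theta else np.empty((0, pv.dim)),
        log_l=np.array(kept_ll),
        log_p=np.array(kept_lp),
        acceptance_rate=(n_acc_post / n_post) if n_post else 0.0,
        seed=seed,
        n_steps=n_steps,
        burn_in=burn_in,
        thinning=thinning,
        best_theta=best_theta,
        max_log_l=float(max_ll),
        step_sigma_final=sigma,
        n_floored_total=n_floored_total,
    )
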
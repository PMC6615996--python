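"""Hybrid Poisson-mixture simulator with a piecewise-deterministic switching rate.

Conditioned on a realization ``s(t)`` of the promoter-state path, the mRNA
copy number of a cell (once initial transients have decayed, ``t >> 1/delta``)
is exactly Poisson with a deterministic rate ``lambda(t)`` obeying the
piecewise-linear ODE

    d lambda / dt = beta_{s(t)} - delta * lambda,   lambda(t_start) = 0.

The time-dependent joint law of (mRNA count m, active-transcription-site
count TS) is therefore a dynamic Poisson mixture: kinetic Monte Carlo
(Gillespie) sampling of promoter paths in the small genetic state space
provides the mixing kernel, and the mRNA dimension never has to be
simulated or truncated.  This removes the stiff, high-dimensional master
equation from the likelihood loop entirely.

The path sampler is vectorized over paths: all pending paths advance one
switching event per iteration, with waiting times clamped at the induction
time (where the U-phase rates switch to the S-phase rates) and at the end
of the window.  Within an event-free interval lambda is propagated by the
exact exponential solution, so no ODE-solver tolerance enters the error
budget; the only error is Monte Carlo, decaying as ``N_s**-1/2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from .model_space import GeneTopology, InductionModel, ParameterSet, build_generator

__all__ = [
    "GeneticPath",
    "MixtureKernel",
    "JointDistribution",
    "stationary_state_distribution",
    "sample_genetic_path",
    "propagate_lambda",
    "build_mixture",
    "ts_count",
    "default_active_set",
    "mixture_to_joint",
    "mixture_pmf_at",
    "total_variation",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def stationary_state_distribution(generator: np.ndarray) -> np.ndarray:
    """Stationary law pi of a CTMC generator: pi Q = 0, pi >= 0, sum pi = 1.

    Raises ``ValueError`` for a reducible (not strongly connected) generator.
    """
    Q = np.asarray(generator, dtype=float)
    S = Q.shape[0]
    if S == 1:
        return np.ones(1)
    adj = csr_matrix((Q - np.diag(np.diag(Q))) > 0)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("generator is reducible; no unique stationary distribution")
    A = np.vstack([Q.T, np.ones(S)])
    b = np.zeros(S + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _initial_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary law when it exists; uniform for a rate-free (frozen) chain."""
    S = Q.shape[0]
    if S == 1:
        return np.ones(1)
    if not np.any(Q - np.diag(np.diag(Q))):
        return np.full(S, 1.0 / S)  # no transitions: every state is absorbing
    return stationary_state_distribution(Q)


def propagate_lambda(lambda0, beta, delta, dt):
    """Exact solution of d(lambda)/dt = beta - delta*lambda after time dt.

    lambda(dt) = beta/delta + (lambda0 - beta/delta) * exp(-delta*dt).
    Vectorized over any broadcastable combination of arguments.
    """
    lambda0 = np.asarray(lambda0, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be >= 0")
    if np.any(np.asarray(delta, dtype=float) <= 0):
        raise ValueError("delta must be > 0")
    fp = np.asarray(beta, dtype=float) / delta
    out = fp + (lambda0 - fp) * np.exp(-np.asarray(delta) * dt)
    return out if out.shape else float(out)


@dataclass
class GeneticPath:
    """A single-allele promoter path: piecewise-constant states on [t_start, t_end].

    ``states[k]`` holds on ``[switch_times[k], switch_times[k+1])`` with the
    convention ``switch_times[0] == t_start`` and an implicit final interval
    ending at ``t_end``.
    """

    switch_times: np.ndarray
    states: np.ndarray
    t_start: float
    t_end: float
    induction_time: float

    def state_at(self, t: float) -> int:
        idx = np.searchsorted(self.switch_times, t, side="right") - 1
        return int(self.states[max(idx, 0)])

    def lambda_at(self, params: ParameterSet, times) -> np.ndarray:
        """Propagate lambda (lambda(t_start) = 0) piecewise along the path."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        # breakpoints: switches plus the induction boundary
        cuts = list(self.switch_times)
        if self.t_start < self.induction_time < self.t_end:
            cuts.append(self.induction_time)
        cuts = np.array(sorted(set(cuts)))
        out = np.empty(len(times))
        for n, t in enumerate(times):
            lam, t_cur = 0.0, self.t_start
            for c in cuts[1:]:
                seg_end = min(c, t)
                if seg_end <= t_cur:
                    break
                phase = "S" if t_cur >= self.induction_time else "U"
                st = self.state_at(t_cur)
                beta = params.value(f"beta_{st}", phase)
                delta = params.delta(phase)
                lam = propagate_lambda(lam, beta, delta, seg_end - t_cur)
                t_cur = seg_end
            if t > t_cur:
                phase = "S" if t_cur >= self.induction_time else "U"
                st = self.state_at(t_cur)
                lam = propagate_lambda(
                    lam, params.value(f"beta_{st}", phase), params.delta(phase), t - t_cur
                )
            out[n] = lam
        return out


def sample_genetic_path(
    params: ParameterSet,
    topology: GeneTopology,
    t_window: tuple[float, float],
    induction_time: float,
    rng,
) -> GeneticPath:
    """Statistically exact single-allele CTMC path via the Gillespie algorithm.

    U-phase rates apply before ``induction_time``, S-phase after; the initial
    state is drawn from the U-phase stationary distribution.
    """
    rng = _as_rng(rng)
    t_start, t_end = map(float, t_window)
    Q = {ph: build_generator(params, topology, ph) for ph in ("U", "S")}
    pi0 = _initial_distribution(Q["U"])
    state = int(rng.choice(topology.n_states, p=pi0))
    t = t_start
    times, states = [t_start], [state]
    while t < t_end:
        phase = "S" if t >= induction_time else "U"
        exit_rate = -Q[phase][state, state]
        dt = rng.exponential(1.0 / exit_rate) if exit_rate > 0 else np.inf
        if t < induction_time <= t + dt:
            t = induction_time  # memoryless: re-draw under the new phase
            continue
        t = t + dt
        if t >= t_end:
            break
        probs = Q[phase][state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(topology.n_states, p=probs))
        times.append(t)
        states.append(state)
    return GeneticPath(
        np.array(times), np.array(states, dtype=int), t_start, t_end, induction_time
    )


@dataclass
class MixtureKernel:
    """The Poisson-mixture mixing kernel: (state, lambda) per path, allele, time.

    ``states`` and ``lam`` have shape ``(n_paths, n_alleles, n_times)``.
    """

    observation_times: np.ndarray
    states: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        if self.states.shape != self.lam.shape:
            raise ValueError("states and lam shapes differ")
        if self.states.ndim != 3:
            raise ValueError("expected (n_paths, n_alleles, n_times) arrays")
        if self.n_paths < 1:
            raise ValueError("kernel must contain at least one path")

    @property
    def n_paths(self) -> int:
        return self.states.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.states.shape[1]

    def lam_total(self, time_index: int) -> np.ndarray:
        """Per-cell total Poisson rate (sum over independent alleles)."""
        return self.lam[:, :, time_index].sum(axis=1)

    def ts(self, time_index: int, active_set) -> np.ndarray:
        return ts_count(self.states[:, :, time_index], active_set)


@numba.njit(cache=True, inline="always")
def _sm_fin(z):
    # splitmix64 finalizer: a high-quality 64-bit mixing function
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@numba.njit(cache=True, inline="always")
def _sm_uniform(stream, k):
    # k-th uniform of a counter-based substream; never exactly 0 or 1
    z = _sm_fin(stream + np.uint64(k) * np.uint64(0x9E3779B97F4A7C15))
    return (np.float64(z >> np.uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@numba.njit(cache=True)
def _kmc_paths(
    n_sims,
    seed,
    exit_rate,  # (2, S) per-phase exit rates
    betas,  # (2, S)
    deltas,  # (2,)
    cum_jump,  # (2, S, S) cumulative jump-destination probabilities
    pi_cum,  # (S,) cumulative initial (stationary) distribution
    t_start,
    induction_time,
    obs,  # sorted observation times; t_end = obs[-1]
):
    """Kinetic Monte Carlo over independent single-allele paths.

    Each path draws from its own counter-based substream keyed by
    (seed, path index, event index), so a fixed seed reproduces every path
    bit-for-bit (common random numbers across likelihood evaluations) and a
    fresh seed yields independent kernels; neither depends on scheduling.
    lambda starts at 0 at t_start and is advanced with the exact exponential
    solution on each constant-state interval; waiting times are clamped
    (without a state jump) at the induction boundary, valid by memorylessness.
    """
    L = obs.shape[0]
    t_end = obs[L - 1]
    out_state = np.zeros((n_sims, L), dtype=np.int64)
    out_lam = np.zeros((n_sims, L))
    for p in range(n_sims):
        stream = _sm_fin(
            np.uint64(seed) * np.uint64(0xD1342543DE82EF95)
            + np.uint64(p + 1) * np.uint64(0xDA942042E4DD58B5)
        )
        k = 0
        u0 = _sm_uniform(stream, k)
        k += 1
        state = 0
        while pi_cum[state] <= u0 and state < pi_cum.shape[0] - 1:
            state += 1
        t = t_start
        lam = 0.0
        obs_i = 0
        while obs_i < L and obs[obs_i] <= t_start:
            out_state[p, obs_i] = state
            out_lam[p, obs_i] = 0.0
            obs_i += 1
        while t < t_end:
            ph = 1 if t >= induction_time else 0
            ex = exit_rate[ph, state]
            ue = _sm_uniform(stream, k)
            uj = _sm_uniform(stream, k + 1)
            k += 2
            jump = True
            if ex > 0.0:
                t_next = t - np.log(ue) / ex
            else:
                t_next = t_end
                jump = False
            if ph == 0 and t_next > induction_time:
                t_next = induction_time
                jump = False
            if t_next > t_end:
                t_next = t_end
                jump = False
            b = betas[ph, state]
            d = deltas[ph]
            fp = b / d
            while obs_i < L and obs[obs_i] <= t_next:
                out_state[p, obs_i] = state
                out_lam[p, obs_i] = fp + (lam - fp) * np.exp(-d * (obs[obs_i] - t))
                obs_i += 1
            lam = fp + (lam - fp) * np.exp(-d * (t_next - t))
            t = t_next
            if jump:
                s_new = 0
                while cum_jump[ph, state, s_new] <= uj and s_new < cum_jump.shape[2] - 1:
                    s_new += 1
                state = s_new
    return out_state, out_lam


def _simulate_lambda_states(
    n_sims: int,
    Q_u: np.ndarray,
    Q_s: np.ndarray,
    beta_u: np.ndarray,
    beta_s: np.ndarray,
    delta_u: float,
    delta_s: float,
    t_start: float,
    induction_time: float,
    obs: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Prepare phase arrays and run the jitted KMC engine for n_sims paths."""
    S = Q_u.shape[0]
    exit_rate = np.stack([-np.diag(Q_u), -np.diag(Q_s)])  # (2, S)
    betas = np.stack([beta_u, beta_s])
    deltas = np.array([delta_u, delta_s])

    def _cum_rows(Q):
        P = Q.copy()
        np.fill_diagonal(P, 0.0)
        tot = P.sum(axis=1)
        P = P / np.where(tot > 0, tot, 1.0)[:, None]
        return np.cumsum(P, axis=1)

    cum = np.stack([_cum_rows(Q_u), _cum_rows(Q_s)])  # (2, S, S)
    pi0 = _initial_distribution(Q_u)
    return _kmc_paths(
        int(n_sims),
        np.uint64(int(seed) % 2**63),
        exit_rate,
        betas,
        deltas,
        cum,
        np.cumsum(pi0),
        float(t_start),
        float(induction_time),
        np.asarray(obs, dtype=float),
    )


def build_mixture(
    params: ParameterSet,
    topology: GeneTopology,
    observation_times,
    n_paths: int,
    induction_time: float = 0.0,
    burn_in: float | None = None,
    rng=None,
    model: InductionModel | None = None,
    seed: int | None = None,
) -> MixtureKernel:
    """Sample the Poisson-mixture kernel: ``n_paths`` cells, each with
    ``n_alleles`` independent promoter paths on ``[-burn_in, max(obs)]``.

    ``burn_in`` is the equilibration time before t = 0 (default ``10/delta``);
    lambda starts at 0 there and the promoter state is drawn from the
    U-phase stationary distribution, so the genetic marginal is exactly
    stationary at the window start.

    Randomness is counter-based per path: pass ``seed`` directly (the same
    seed reproduces every path bit-for-bit and gives common random numbers
    across parameter values), or pass ``rng``/an int there to derive one.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if model is not None:
        params.validate_against(model)
    obs = np.sort(np.asarray(observation_times, dtype=float))
    if obs.size == 0:
        raise ValueError("need at least one observation time")
    if burn_in is None:
        burn_in = 10.0 / params.delta("U")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    t_start = -float(burn_in)
    if obs.min() < t_start:
        raise ValueError("observation time outside simulation window")
    if seed is None:
        seed = int(_as_rng(rng).integers(2**63)) if rng is not None else 0
    n_all = topology.n_alleles
    states, lam = _simulate_lambda_states(
        n_paths * n_all,
        build_generator(params, topology, "U"),
        build_generator(params, topology, "S"),
        params.beta("U"),
        params.beta("S"),
        params.delta("U"),
        params.delta("S"),
        t_start,
        float(induction_time),
        obs,
        seed,
    )
    shape = (n_paths, n_all, len(obs))
    return MixtureKernel(obs, states.reshape(shape), lam.reshape(shape))


def default_active_set(topology: GeneTopology) -> frozenset[int]:
    """States counted as visible transcription sites: all but the basal state 0."""
    return frozenset(range(1, topology.n_states))


def ts_count(allele_states, active_set) -> np.ndarray:
    """Number of alleles currently in a high-activity state.

    ``allele_states`` has alleles on its last axis; returns an integer array
    with that axis summed out.
    """
    st = np.asarray(allele_states)
    active = np.isin(st, list(active_set))
    return active.sum(axis=-1).astype(np.int64)


@dataclass
class JointDistribution:
    """P(m, TS) per observation time on a truncated support m in [0, m_max].

    ``probs`` has shape ``(n_times, m_max + 1, n_ts + 1)``; ``tail_mass``
    records the per-time probability beyond the truncation.
    """

    times: np.ndarray
    probs: np.ndarray
    tail_mass: np.ndarray = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.tail_mass is None:
            self.tail_mass = 1.0 - self.probs.sum(axis=(1, 2))
        if np.any(self.probs < -1e-12):
            raise ValueError("negative probabilities")

    @property
    def m_max(self) -> int:
        return self.probs.shape[1] - 1

    @property
    def n_ts(self) -> int:
        return self.probs.shape[2] - 1

    def marginal_m(self, time_index: int) -> np.ndarray:
        return self.probs[time_index].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l, t in enumerate(self.times):
            P = self.probs[l]
            m_idx, ts_idx = np.nonzero(P)
            rows.append(
                pd.DataFrame(
                    {"time": t, "m": m_idx, "TS": ts_idx, "probability": P[m_idx, ts_idx]}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path, metadata: dict | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if metadata is not None:
            meta = dict(metadata)
            meta["tail_mass"] = [float(x) for x in self.tail_mass]
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2, default=str)


def poisson_logpmf(m, lam):
    """log Poisson pmf, safe at lam = 0 (point mass at m = 0)."""
    m = np.asarray(m, dtype=float)
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = m * np.log(lam) - lam - gammaln(m + 1.0)
    if np.any(lam == 0):
        zero = np.broadcast_to(lam == 0, out.shape)
        m_b = np.broadcast_to(m, out.shape)
        out = np.where(zero, np.where(m_b == 0, 0.0, -np.inf), out)
    return out


def default_m_support(kernel: MixtureKernel) -> int:
    """Truncation covering every component's 10-sigma Poisson tail."""
    hi = 0.0
    for l in range(len(kernel.observation_times)):
        lam = kernel.lam_total(l)
        hi = max(hi, float(np.max(lam + 10.0 * np.sqrt(lam))))
    return int(np.ceil(hi)) + 10


def mixture_to_joint(
    kernel: MixtureKernel,
    active_set,
    m_support: int | None = None,
) -> JointDistribution:
    """Convolve the mixture kernel into the joint snapshot law P(m, TS, t).

    P(m, TS) = (1/N_s) sum_k 1[TS_k = TS] * Poisson(m; sum_alleles lambda_k).
    """
    M = default_m_support(kernel) if m_support is None else int(m_support)
    L = len(kernel.observation_times)
    n_ts = kernel.n_alleles
    m_grid = np.arange(M + 1, dtype=np.float64)
    log_fact = gammaln(m_grid + 1.0)
    probs = np.zeros((L, M + 1, n_ts + 1))
    for l in range(L):
        lam = kernel.lam_total(l)
        ts = kernel.ts(l, active_set)
        for v in range(n_ts + 1):
            lam_v = np.ascontiguousarray(lam[ts == v])
            if lam_v.size == 0:
                continue
            acc = np.zeros(M + 1)
            _accumulate_poisson_mixture(m_grid, log_fact, lam_v, acc)
            probs[l, :, v] = acc / kernel.n_paths
    return JointDistribution(kernel.observation_times, probs)


@numba.njit(cache=True)
def _accumulate_poisson_mixture(bm, log_fact, lam_v, out):
    """Sum Poisson pmfs over mixture components at sorted integer bins.

    Components only touch bins within 12 standard deviations of their rate;
    contributions outside are below ~1e-10 and are left at zero (they fall
    under the likelihood floor regardless).
    """
    nb = bm.shape[0]
    for k in range(lam_v.shape[0]):
        lam = lam_v[k]
        if lam <= 0.0:
            if nb > 0 and bm[0] == 0:
                out[0] += 1.0
            continue
        sig = np.sqrt(lam)
        lo = np.searchsorted(bm, lam - 12.0 * sig - 12.0)
        hi = np.searchsorted(bm, lam + 12.0 * sig + 12.0)
        ll = np.log(lam)
        for j in range(lo, hi):
            out[j] += np.exp(bm[j] * ll - lam - log_fact[j])


def mixture_pmf_at(kernel: MixtureKernel, bins, time_index: int, active_set) -> np.ndarray:
    """Joint probabilities at selected (m, TS) bins without a full support.

    Evaluates the same mixture as :func:`mixture_to_joint`, restricted to
    ``bins`` — the hot path of the snapshot likelihood.
    """
    bins = list(bins)
    if not bins:
        return np.zeros(0)
    bm = np.array([b[0] for b in bins], dtype=np.int64)
    bts = np.array([b[1] for b in bins], dtype=np.int64)
    lam = kernel.lam_total(time_index)
    ts = kernel.ts(time_index, active_set)
    out = np.zeros(len(bins))
    for v in np.unique(bts):
        sel_bins = np.flatnonzero(bts == v)
        lam_v = np.ascontiguousarray(lam[ts == v])
        if lam_v.size == 0:
            continue
        order = np.argsort(bm[sel_bins], kind="stable")
        mv = np.ascontiguousarray(bm[sel_bins][order], dtype=np.float64)
        acc = np.zeros(mv.size)
        _accumulate_poisson_mixture(mv, gammaln(mv + 1.0), lam_v, acc)
        out[sel_bins[order]] = acc / kernel.n_paths
    return out


def total_variation(p, q) -> float:
    """Total-variation distance between two pmfs on (possibly ragged) supports.

    Arrays are zero-padded to a common shape; unassigned tail mass counts as
    disagreement, i.e. TV = 0.5 * (sum |p - q| + |tail_p - tail_q|) is bounded
    by the padded-sum formula used here.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    shape = tuple(max(a, b) for a, b in zip(p.shape, q.shape))
    pp = np.zeros(shape)
    qq = np.zeros(shape)
    pp[tuple(slice(0, s) for s in p.shape)] = p
    qq[tuple(slice(0, s) for s in q.shape)] = q
    return 0.5 * float(np.abs(pp - qq).sum())
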
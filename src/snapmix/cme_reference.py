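"""Truncated chemical-master-equation oracle for the joint (allele pair, mRNA) law.

The CME over the ordered allele-pair state (s1, s2) and the mRNA count
m <= M is a linear ODE dp/dt = A p with a sparse generator of dimension
S^2 (M + 1).  Synthesis flux out of m = M leaves the truncated system and
the lost mass is tracked, so the column sums of A vanish everywhere except
at that boundary.  Forward integration uses a stiff (BDF) solver; the
result serves as the accuracy oracle for the hybrid Poisson-mixture
simulator and as the efficiency baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import coo_matrix, csr_matrix
from scipy.special import gammaln, hyp1f1

from .model_space import GeneTopology, ParameterSet, build_generator
from .pmpdmsr import JointDistribution, stationary_state_distribution

__all__ = [
    "TruncatedCME",
    "build_truncated_generator",
    "default_truncation",
    "stationary_initial_condition",
    "integrate_cme",
    "CMESolution",
    "joint_from_cme",
    "beta_poisson_pmf",
]


@dataclass
class TruncatedCME:
    """Sparse generator for one phase over states (s1, ..., s_nalleles, m)."""

    params: ParameterSet
    topology: GeneTopology
    phase: str
    M: int
    generator: csr_matrix

    @property
    def dimension(self) -> int:
        return self.topology.n_states ** self.topology.n_alleles * (self.M + 1)

    def index(self, allele_states, m) -> int:
        S = self.topology.n_states
        s = 0
        for a in allele_states:
            s = s * S + int(a)
        return s * (self.M + 1) + int(m)


def default_truncation(params: ParameterSet, topology: GeneTopology) -> int:
    """Truncation holding the fixed-point Poisson mass: 2*mu + 10*sqrt(mu)."""
    mu = 0.0
    for ph in ("U", "S"):
        b = params.beta(ph).max() * topology.n_alleles
        mu = max(mu, b / params.delta(ph))
    return int(np.ceil(2.0 * mu + 10.0 * np.sqrt(mu)))


def build_truncated_generator(
    params: ParameterSet, topology: GeneTopology, phase: str, M: int
) -> TruncatedCME:
    """Assemble the sparse CME generator A (convention dp/dt = A p).

    Reactions: per-allele promoter switching at kappa_ij, synthesis
    m -> m+1 at beta_{s1} + beta_{s2} (+...), degradation m -> m-1 at
    delta*m.  Synthesis out of m = M is a tracked leak: it contributes to
    the diagonal but has no destination state.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    S = topology.n_states
    nA = topology.n_alleles
    Q1 = build_generator(params, topology, phase)
    beta = params.beta(phase)
    delta = params.delta(phase)
    n_gen = S**nA
    dim = n_gen * (M + 1)

    gen_states = np.array(
        np.unravel_index(np.arange(n_gen), (S,) * nA)
    ).T  # (n_gen, nA)
    beta_tot = beta[gen_states].sum(axis=1)  # (n_gen,)
    m = np.arange(M + 1)

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    base = np.arange(n_gen) * (M + 1)
    # promoter switching, one allele at a time
    for a in range(nA):
        for i in range(S):
            for j in range(S):
                if i == j or Q1[i, j] == 0:
                    continue
                sel = np.flatnonzero(gen_states[:, a] == i)
                dest_states = gen_states[sel].copy()
                dest_states[:, a] = j
                dest = np.zeros(sel.size, dtype=np.int64)
                for aa in range(nA):
                    dest = dest * S + dest_states[:, aa]
                for g_from, g_to in zip(sel, dest):
                    add(base[g_to] + m, base[g_from] + m, np.full(M + 1, Q1[i, j]))
    # synthesis: (g, m) -> (g, m+1) at beta_tot[g]; the m = M event leaks
    for g in range(n_gen):
        if beta_tot[g] > 0:
            add(base[g] + m[1:], base[g] + m[:-1], np.full(M, beta_tot[g]))
    # degradation: (g, m) -> (g, m-1) at delta*m
    for g in range(n_gen):
        add(base[g] + m[:-1], base[g] + m[1:], delta * m[1:])

    rows = np.concatenate([np.atleast_1d(r) for r in rows])
    cols = np.concatenate([np.atleast_1d(c) for c in cols])
    vals = np.concatenate([np.atleast_1d(v) for v in vals])
    A = coo_matrix((vals, (rows, cols)), shape=(dim, dim)).tocsr()
    # diagonal: total outflow per column, including the leaked synthesis at m = M
    out = np.asarray(A.sum(axis=0)).ravel()
    leak = np.zeros(dim)
    for g in range(n_gen):
        leak[base[g] + M] = beta_tot[g]
    diag = -(out + leak)
    A = (A + coo_matrix((diag, (np.arange(dim), np.arange(dim))), shape=(dim, dim))).tocsr()
    return TruncatedCME(params, topology, phase, M, A)


def stationary_initial_condition(cme: TruncatedCME) -> np.ndarray:
    """Product initial law: stationary promoter states, zero mRNA."""
    topo = cme.topology
    Q1 = build_generator(cme.params, topo, cme.phase)
    pi = stationary_state_distribution(Q1) if topo.n_states > 1 else np.ones(1)
    pg = pi
    for _ in range(topo.n_alleles - 1):
        pg = np.outer(pg, pi).ravel()
    p0 = np.zeros(cme.dimension)
    p0[np.arange(pg.size) * (cme.M + 1)] = pg
    return p0


@dataclass
class CMESolution:
    times: np.ndarray
    P: np.ndarray  # (n_times, dim)
    topology: GeneTopology
    M: int
    mass: np.ndarray  # per-time retained probability mass

    def reshaped(self, time_index: int) -> np.ndarray:
        S = self.topology.n_states
        shape = (S,) * self.topology.n_alleles + (self.M + 1,)
        return self.P[time_index].reshape(shape)


def integrate_cme(
    cme,
    p0: np.ndarray,
    t_grid,
    induction_time: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    t0: float | None = None,
) -> CMESolution:
    """Stiff forward integration of dp/dt = A p on t_grid.

    ``cme`` is either a single :class:`TruncatedCME` (no parameter switch) or
    a ``(U_phase, S_phase)`` pair, in which case integration is split at
    ``induction_time``.  Mass loss through the truncation boundary is
    recorded in ``CMESolution.mass``; a loss above 1e-6 raises a warning.
    """
    import warnings

    t_grid = np.sort(np.asarray(t_grid, dtype=float))
    if isinstance(cme, TruncatedCME):
        cme_u = cme_s = cme
        induction_time = np.inf if induction_time is None else induction_time
    else:
        cme_u, cme_s = cme
        if induction_time is None:
            raise ValueError("induction_time required with a (U, S) generator pair")
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError("p0 must be a probability vector")
    t_cur = float(t_grid[0]) if t0 is None else float(t0)

    out = np.empty((len(t_grid), p0.size))
    p = p0.copy()

    def _run(A, t_from, t_to, evals):
        nonlocal p
        if t_to <= t_from:
            return
        sol = solve_ivp(
            lambda t, y: A @ y,
            (t_from, t_to),
            p,
            method="BDF",
            t_eval=[t for t in evals if t_from < t <= t_to] or None,
            jac=A,
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"CME integration failed: {sol.message}")
        for k, t in enumerate(sol.t):
            idx = np.flatnonzero(np.isclose(t_grid, t))
            for i in idx:
                out[i] = sol.y[:, k]
        p = sol.y[:, -1] if sol.y.shape[1] else p

    for i, t in enumerate(t_grid):
        if np.isclose(t, t_cur):
            out[i] = p
    t_end = float(t_grid[-1])
    if t_cur < induction_time < t_end:
        _run(cme_u.generator, t_cur, induction_time, t_grid)
        _run(cme_s.generator, induction_time, t_end, t_grid)
    else:
        A = cme_s.generator if t_cur >= induction_time else cme_u.generator
        _run(A, t_cur, t_end, t_grid)

    mass = out.sum(axis=1)
    if np.any(mass < 1.0 - 1e-6):
        warnings.warn(
            f"CME truncation lost {1.0 - mass.min():.2e} probability mass; "
            "consider a larger M",
            stacklevel=2,
        )
    topo = cme_u.topology
    return CMESolution(t_grid, out, topo, cme_u.M, mass)


def joint_from_cme(solution: CMESolution, active_set) -> JointDistribution:
    """Marginalize allele-pair states onto the (m, TS) observable."""
    topo = solution.topology
    S = topo.n_states
    nA = topo.n_alleles
    n_gen = S**nA
    gen_states = np.array(np.unravel_index(np.arange(n_gen), (S,) * nA)).T
    ts_of_gen = np.isin(gen_states, list(active_set)).sum(axis=1)
    L = len(solution.times)
    probs = np.zeros((L, solution.M + 1, nA + 1))
    for l in range(L):
        P = solution.P[l].reshape(n_gen, solution.M + 1)
        for v in range(nA + 1):
            probs[l, :, v] = P[ts_of_gen == v].sum(axis=0)
    return JointDistribution(np.asarray(solution.times), probs)


def beta_poisson_pmf(m, k_on: float, k_off: float, beta: float, delta: float):
    """Stationary mRNA law of the single-allele two-state (telegraph) model.

    The classical result of Peccoud & Ycart: mixing Poisson(lam_max * x)
    over x ~ Beta(a, b) with a = k_on/delta, b = k_off/delta and
    lam_max = beta/delta gives

        P(m) = lam_max^m / m! * (a)_m / (a+b)_m * 1F1(a+m; a+b+m; -lam_max),

    where (x)_m is the rising factorial.  Used as the closed-form oracle for
    the stationary limits of both simulation engines.
    """
    m = np.atleast_1d(np.asarray(m, dtype=float))
    a = k_on / delta
    b = k_off / delta
    lam = beta / delta
    log_coef = (
        m * np.log(lam)
        - gammaln(m + 1.0)
        + gammaln(a + m)
        - gammaln(a)
        + gammaln(a + b)
        - gammaln(a + b + m)
    )
    out = np.exp(log_coef) * hyp1f1(a + m, a + b + m, -lam)
    return out if out.size > 1 else float(out[0])
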
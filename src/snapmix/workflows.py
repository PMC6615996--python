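"""End-to-end inference workflows: fit one model, or rank a model set.

These functions tie the simulator, likelihood, sampler and evidence modules
into the snapshot-inference pipeline: generate/load a histogram, run an MH
chain per candidate induction model, re-evaluate the stored draws with a
larger mixture kernel, and score each model by IS-HME evidence, BIC and
AIC.  Model ranking is embarrassingly parallel over models; per-model seeds
are derived from the master seed and the model code, never from scheduling
order, so results are independent of the worker count.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import SnapshotHistogram
from .mcmc import (
    ParameterVector,
    PosteriorChain,
    PriorSpec,
    ProposalSpec,
    SnapshotLikelihoodEngine,
    run_chain,
)
from .model_selection import aic, bic, is_hme_evidence, model_weights
from .model_space import GeneTopology, ParameterSet, parse_code

__all__ = ["FitConfig", "FitResult", "fit_model", "select_models"]


@dataclass
class FitConfig:
    """Settings shared by fit and select runs."""

    induction_time: float = 10.0
    n_paths: int = 10_000
    n_paths_final: int = 100_000
    kernel_mode: str = "fresh"  # 'fresh' (pseudo-marginal), 'fixed' (CRN), 'mcwm'
    n_steps: int = 1_000_000
    burn_in: int = 100_000
    thinning: int = 100
    init: str = "moments"  # 'moments' (global moment match + polish) or 'prior'
    n_init: int = 50
    n_anneal: int = 300
    init_maxfun: int = 20000
    polish_maxfev: int = 1200
    step_sigma: float = 0.05
    prior_bounds: tuple[float, float] = (1e-2, 1e3)
    # optional tighter upper bound for switching rates (kappa_*): fast
    # switching self-averages and is both unidentifiable from snapshots and
    # expensive to simulate, so desk-scale runs cap it
    switch_rate_upper: float | None = None
    alpha: float = 0.25
    compute_evidence: bool = True
    active_set: tuple[int, ...] | None = None
    sim_burn_in: float | None = None
    free_mask: dict[str, bool] = field(
        default_factory=lambda: {"beta_0": False, "delta": False}
    )


@dataclass
class FitResult:
    code: str
    chain: PosteriorChain
    log_l_final: np.ndarray  # draws re-evaluated at n_paths_final
    log_evidence: float
    evidence_se: float
    max_log_l: float
    k: int
    n: int
    bic: float
    aic: float


def _seed_for(master_seed: int, code: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), int(code, 2)])


def reevaluate_draws(
    chain: PosteriorChain,
    pv: ParameterVector,
    engine: SnapshotLikelihoodEngine,
    n_paths: int,
    seed,
) -> np.ndarray:
    """Recompute log-likelihoods of stored draws with a larger kernel."""
    rng = np.random.default_rng(seed)
    out = np.empty(chain.n_draws)
    for i, theta in enumerate(chain.draws):
        out[i], _ = engine.log_likelihood(
            pv.to_params(theta), int(rng.integers(2**31 - 1)), n_paths=n_paths
        )
    return out


def fit_model(
    histogram: SnapshotHistogram,
    code: str,
    base_params: ParameterSet,
    config: FitConfig,
    seed: int = 0,
) -> FitResult:
    """Posterior sampling plus evidence/criteria for one induction model."""
    topo = base_params.topology
    model = parse_code(code, topo)
    base = ParameterSet(
        topo,
        dict(base_params.unstimulated),
        dict(base_params.unstimulated),  # S starts equal; induced coords add the rest
        dict(config.free_mask) if config.free_mask else dict(base_params.free_mask),
    )
    pv = ParameterVector(model, base)
    lower = np.full(pv.dim, config.prior_bounds[0])
    upper = np.full(pv.dim, config.prior_bounds[1])
    if config.switch_rate_upper is not None:
        is_switch = np.array([n.startswith("kappa") for n in pv.names])
        upper[is_switch] = np.minimum(upper[is_switch], config.switch_rate_upper)
    prior = PriorSpec(lower, upper)
    proposal = ProposalSpec(step_sigma=config.step_sigma)
    ss = _seed_for(seed, code)
    s_chain, s_engine, s_final = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]
    engine = SnapshotLikelihoodEngine(
        histogram,
        topo,
        induction_time=config.induction_time,
        n_paths=config.n_paths,
        burn_in=config.sim_burn_in,
        active_set=config.active_set,
        kernel_mode="fixed" if config.kernel_mode == "fixed" else "fresh",
        base_seed=s_engine,
    )
    # mode finding happens on one fixed common-random-number surface so the
    # optimizer sees a deterministic objective
    polish_engine = SnapshotLikelihoodEngine(
        histogram,
        topo,
        induction_time=config.induction_time,
        n_paths=config.n_paths,
        burn_in=config.sim_burn_in,
        active_set=config.active_set,
        kernel_mode="fixed",
        base_seed=s_engine,
    )
    params0 = base
    n_init, n_anneal = config.n_init, config.n_anneal
    if config.init == "moments":
        from scipy.optimize import minimize

        from .moments import moment_initializer

        candidates = moment_initializer(
            histogram,
            pv.to_params,
            pv.dim,
            topo,
            config.induction_time,
            bounds=(prior.lower, prior.upper),
            seed=s_final,
            burn_in=config.sim_burn_in,
            active_set=config.active_set,
            maxfun=config.init_maxfun,
        )
        lo10 = np.log10(prior.lower)
        hi10 = np.log10(prior.upper)

        def _negll(x):
            th = 10.0 ** np.clip(x, lo10, hi10)
            return -polish_engine.log_likelihood(pv.to_params(th), 0)[0]

        # adjudicate moment-matching candidates under the true likelihood,
        # then polish the winner
        scored = []
        for cand in candidates:
            r = minimize(
                _negll,
                np.log10(cand),
                method="Nelder-Mead",
                options=dict(maxfev=max(config.polish_maxfev // 3, 200), fatol=0.5),
            )
            scored.append((r.fun, r.x))
        scored.sort(key=lambda t: t[0])
        res = minimize(
            _negll,
            scored[0][1],
            method="Nelder-Mead",
            options=dict(maxfev=config.polish_maxfev, fatol=0.2, xatol=1e-4),
        )
        params0 = pv.to_params(10.0 ** np.clip(res.x, lo10, hi10))
        n_init = n_anneal = 0
    chain = run_chain(
        histogram,
        model,
        params0,
        prior,
        proposal,
        engine,
        n_steps=config.n_steps,
        burn_in=config.burn_in,
        thinning=config.thinning,
        seed=s_chain,
        n_init=n_init,
        n_anneal=n_anneal,
        reevaluate_current=(config.kernel_mode == "mcwm"),
    )
    # evidence from draws re-scored with an independent, larger kernel
    if config.compute_evidence:
        final_engine = SnapshotLikelihoodEngine(
            histogram,
            topo,
            induction_time=config.induction_time,
            n_paths=config.n_paths_final,
            burn_in=config.sim_burn_in,
            active_set=config.active_set,
            kernel_mode="fresh",
        )
        log_l_final = reevaluate_draws(
            chain, pv, final_engine, config.n_paths_final, s_final
        )
        ev = is_hme_evidence(chain, prior, alpha=config.alpha, log_l=log_l_final)
        ev_log_z, ev_se = ev.log_evidence, ev.standard_error
        max_ll = float(log_l_final.max())
    else:
        log_l_final = chain.log_l
        ev_log_z, ev_se = np.nan, np.nan
        max_ll = float(chain.max_log_l)
    k = pv.free_count()
    n = histogram.total_cells
    return FitResult(
        code=code,
        chain=chain,
        log_l_final=log_l_final,
        log_evidence=ev_log_z,
        evidence_se=ev_se,
        max_log_l=max_ll,
        k=k,
        n=n,
        bic=bic(max_ll, k, n),
        aic=aic(max_ll, k),
    )


def _fit_one(args):
    histogram, code, base_params, config, seed = args
    return fit_model(histogram, code, base_params, config, seed)


def select_models(
    histogram: SnapshotHistogram,
    codes,
    base_params: ParameterSet,
    config: FitConfig,
    seed: int = 0,
    n_workers: int = 1,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit every candidate code and rank by evidence, BIC and AIC weights.

    Returns the ranking table (sorted by decreasing IS-HME weight) and the
    per-model fit results.  Output is invariant to ``n_workers``.
    """
    codes = list(dict.fromkeys(codes))
    jobs = [(histogram, c, base_params, config, seed) for c in codes]
    if n_workers > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(_fit_one, jobs))
    else:
        results = [_fit_one(j) for j in jobs]
    by_code = {r.code: r for r in results}
    w_hme = model_weights({c: by_code[c].log_evidence for c in codes}, "evidence")
    w_bic = model_weights({c: by_code[c].bic for c in codes}, "bic")
    w_aic = model_weights({c: by_code[c].aic for c in codes}, "aic")
    wh = dict(zip(w_hme.codes, w_hme.weights))
    wb = dict(zip(w_bic.codes, w_bic.weights))
    wa = dict(zip(w_aic.codes, w_aic.weights))
    rows = [
        {
            "code": c,
            "logZ": by_code[c].log_evidence,
            "SE": by_code[c].evidence_se,
            "maxLogL": by_code[c].max_log_l,
            "k": by_code[c].k,
            "BIC": by_code[c].bic,
            "AIC": by_code[c].aic,
            "w_HME": wh[c],
            "w_BIC": wb[c],
            "w_AIC": wa[c],
        }
        for c in codes
    ]
    table = (
        pd.DataFrame(rows)
        .sort_values("w_HME", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return table, by_code
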
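"""Non-binding efficiency comparison: hybrid Poisson-mixture engine vs CME.

Times one likelihood-workflow step for each engine — compute the joint
(m, TS) distribution at the benchmark observation times and evaluate the
snapshot log-likelihood of a synthetic data set — and reports the runtime
ratio.  The ratio is hardware- and size-dependent and is reported for
orientation only.

Usage: python scripts/benchmark_speed.py [--npaths 100000] [--n-cells 1000]
"""

import argparse
import time

import numpy as np

from snapmix.cme_reference import (
    build_truncated_generator,
    default_truncation,
    integrate_cme,
    joint_from_cme,
    stationary_initial_condition,
)
from snapmix.likelihood import log_likelihood
from snapmix.pmpdmsr import build_mixture, default_active_set, mixture_pmf_at
from snapmix.synthetic_data import default_benchmark, generate_dataset


def benchmark(n_paths: int = 100_000, n_cells: int = 1000, seed: int = 0):
    design = default_benchmark("00110000", n_cells, seed=seed)
    hist = generate_dataset(design)
    params, topo = design.gt_params, design.gt_params.topology
    times = hist.observation_times
    active = default_active_set(topo)
    bins = [hist.bin_arrays(l) for l in range(len(times))]

    # warm up the jitted kernels so compilation is not timed
    build_mixture(params, topo, times, 100, induction_time=10.0, seed=seed)

    t0 = time.perf_counter()
    kernel = build_mixture(params, topo, times, n_paths, induction_time=10.0, seed=seed)
    probs = [
        mixture_pmf_at(kernel, list(zip(m, ts)), l, active)
        for l, (m, ts, _) in enumerate(bins)
    ]
    ll_hybrid = log_likelihood(hist, probs).total
    t_hybrid = time.perf_counter() - t0

    t0 = time.perf_counter()
    M = default_truncation(params, topo)
    cme_u = build_truncated_generator(params, topo, "U", M)
    cme_s = build_truncated_generator(params, topo, "S", M)
    sol = integrate_cme(
        (cme_u, cme_s), stationary_initial_condition(cme_u), times,
        induction_time=10.0, t0=-10.0,
    )
    joint = joint_from_cme(sol, active)
    probs_cme = [
        np.array([joint.probs[l, m_i, ts_i] for m_i, ts_i in zip(m, ts)])
        for l, (m, ts, _) in enumerate(bins)
    ]
    ll_cme = log_likelihood(hist, probs_cme).total
    t_cme = time.perf_counter() - t0

    return {
        "t_hybrid_s": t_hybrid,
        "t_cme_s": t_cme,
        "speedup": t_cme / t_hybrid,
        "logL_hybrid": ll_hybrid,
        "logL_cme": ll_cme,
        "n_paths": n_paths,
        "cme_dimension": cme_u.dimension,
    }


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--npaths", type=int, default=100_000)
    ap.add_argument("--n-cells", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    out = benchmark(args.npaths, args.n_cells, args.seed)
    print(
        f"hybrid: {out['t_hybrid_s']:.2f} s   "
        f"CME ({out['cme_dimension']} ODEs): {out['t_cme_s']:.2f} s   "
        f"speedup: {out['speedup']:.1f}x"
    )
    print(
        f"logL hybrid {out['logL_hybrid']:.2f} vs CME {out['logL_cme']:.2f} "
        f"(difference {out['logL_hybrid'] - out['logL_cme']:+.2f})"
    )


if __name__ == "__main__":
    main()
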
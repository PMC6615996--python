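"""Ground-truth snapshot data sets for benchmarking the inference stack.

The benchmark emulates a dynamic smFISH induction experiment on a diploid
3-state gene: N cells are fixed and imaged at each of 4 observation times
(one just before induction, three after), and each cell contributes one
(m, TS) observation.  Cells are sampled by simulating one independent pair
of allele paths per cell directly with the path engine — so data generation
never depends on any mRNA-support truncation — and drawing
m ~ Poisson(lambda_total) at the cell's observation time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .likelihood import SnapshotHistogram
from .model_space import GeneTopology, InductionModel, ParameterSet, parse_code
from .pmpdmsr import build_mixture, default_active_set, ts_count

__all__ = [
    "ExperimentDesign",
    "generate_dataset",
    "default_benchmark",
    "BENCHMARK_BASE_RATES",
]

# Canonical 3-state benchmark rates (kappa_01, kappa_12, kappa_21, kappa_10,
# beta_0, beta_1, beta_2, delta), in units of the mRNA lifetime (delta = 1).
BENCHMARK_BASE_RATES = (0.5, 0.5, 5.0, 5.0, 20.0, 150.0, 300.0, 1.0)

# Stimulated values for the two benchmark ground-truth induction models:
# 00110000 slows both downward rates; 11000000 speeds both upward rates 10x.
_GT_STIMULATED = {
    "00110000": {"kappa_21": 0.5, "kappa_10": 0.5},
    "11000000": {"kappa_01": 5.0, "kappa_12": 5.0},
}


@dataclass
class ExperimentDesign:
    """Fully specified synthetic induction experiment."""

    observation_times: np.ndarray
    cells_per_time: int
    induction_time: float
    gt_model: InductionModel
    gt_params: ParameterSet
    seed: int = 0
    burn_in: float | None = None
    active_set: frozenset | None = field(default=None)

    def __post_init__(self):
        self.observation_times = np.sort(
            np.asarray(self.observation_times, dtype=float)
        )
        if self.observation_times.size == 0:
            raise ValueError("need at least one observation time")
        if self.cells_per_time < 1:
            raise ValueError("cells_per_time must be >= 1")
        self.gt_params.validate_against(self.gt_model)
        if self.active_set is None:
            self.active_set = default_active_set(self.gt_params.topology)

    def manifest(self) -> dict:
        return {
            "gt_code": self.gt_model.code,
            "n_states": self.gt_params.topology.n_states,
            "n_alleles": self.gt_params.topology.n_alleles,
            "observation_times": [float(t) for t in self.observation_times],
            "cells_per_time": int(self.cells_per_time),
            "induction_time": float(self.induction_time),
            "seed": int(self.seed),
            "params_U": self.gt_params.unstimulated,
            "params_S": self.gt_params.stimulated,
            "active_set": sorted(self.active_set),
        }


def generate_dataset(design: ExperimentDesign) -> SnapshotHistogram:
    """Sample one histogram: N independent cells per observation time.

    Reproducible byte-for-byte for a fixed ``design.seed``.
    """
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(len(design.observation_times))
    topo = design.gt_params.topology
    bins = []
    for t_l, child in zip(design.observation_times, children):
        rng = np.random.default_rng(child)
        kernel = build_mixture(
            design.gt_params,
            topo,
            [t_l],
            design.cells_per_time,
            induction_time=design.induction_time,
            burn_in=design.burn_in,
            rng=rng,
        )
        lam = kernel.lam_total(0)
        ts = ts_count(kernel.states[:, :, 0], design.active_set)
        m = rng.poisson(lam)
        table: dict[tuple[int, int], int] = {}
        keys, counts = np.unique(np.stack([m, ts], axis=1), axis=0, return_counts=True)
        for (mm, tt), c in zip(keys, counts):
            table[(int(mm), int(tt))] = int(c)
        bins.append(table)
    return SnapshotHistogram(design.observation_times, bins)


def write_dataset(design: ExperimentDesign, histogram: SnapshotHistogram, path) -> None:
    histogram.to_tsv(path)
    with open(str(path) + ".json", "w") as fh:
        json.dump(design.manifest(), fh, indent=2)


def default_benchmark(
    gt_code: str,
    N: int,
    seed: int = 0,
    observation_times=(9.9, 11.0, 13.0, 16.0),
    induction_time: float = 10.0,
    free_mask: dict[str, bool] | None = None,
) -> ExperimentDesign:
    """The canonical diploid 3-state benchmark design for a ground-truth code.

    Rates are the canonical benchmark values (delta = 1 sets the time unit);
    induction at t = 10 with one pre-induction snapshot and three
    post-induction snapshots spanning ~6 mRNA lifetimes.  ``gt_code`` must
    be one of the two benchmark ground truths, '00110000' or '11000000'.
    """
    gt_code = str(gt_code)
    if gt_code not in _GT_STIMULATED:
        raise ValueError(
            f"no benchmark parameters for code {gt_code!r}; "
            f"known: {sorted(_GT_STIMULATED)}"
        )
    if N < 1:
        raise ValueError("N must be >= 1")
    topo = GeneTopology(n_states=3, n_alleles=2)
    model = parse_code(gt_code, topo)
    if free_mask is None:
        free_mask = {"beta_0": False, "delta": False}
    params = ParameterSet.from_sequence(
        topo, BENCHMARK_BASE_RATES, _GT_STIMULATED[gt_code], free_mask
    )
    return ExperimentDesign(
        observation_times=np.asarray(observation_times, dtype=float),
        cells_per_time=int(N),
        induction_time=induction_time,
        gt_model=model,
        gt_params=params,
        seed=seed,
    )
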
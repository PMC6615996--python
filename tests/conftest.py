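import numpy as np
import pytest

from snapmix.model_space import GeneTopology, ParameterSet

# canonical 3-state diploid benchmark values, delta = 1 sets the time unit
BENCHMARK_RATES = (0.5, 0.5, 5.0, 5.0, 20.0, 150.0, 300.0, 1.0)
BENCHMARK_STIMULATED = {"kappa_21": 0.5, "kappa_10": 0.5}


@pytest.fixture(scope="session")
def topo3():
    return GeneTopology(n_states=3, n_alleles=2)


@pytest.fixture(scope="session")
def topo3_single():
    return GeneTopology(n_states=3, n_alleles=1)


@pytest.fixture(scope="session")
def bench_params(topo3):
    return ParameterSet.from_sequence(topo3, BENCHMARK_RATES, BENCHMARK_STIMULATED)


@pytest.fixture(scope="session")
def constitutive_params():
    """Single-state, single-allele gene expressing at beta = 20, delta = 1."""
    topo = GeneTopology(n_states=1, n_alleles=1)
    return topo, ParameterSet(topo, {"beta_0": 20.0, "delta": 1.0})


@pytest.fixture(scope="session")
def telegraph_params():
    """Two-state single-allele telegraph gene (off/on switching)."""
    topo = GeneTopology(n_states=2, n_alleles=1)
    params = ParameterSet.from_sequence(topo, (1.0, 2.0, 0.0, 60.0, 1.0))
    return topo, params


@pytest.fixture(scope="session")
def benchmark_histogram():
    """Small synthetic induction data set (N = 200 cells x 4 times)."""
    from snapmix.synthetic_data import default_benchmark, generate_dataset

    design = default_benchmark("00110000", 200, seed=42)
    return design, generate_dataset(design)
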
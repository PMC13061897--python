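import numpy as np
import pytest

from coculture import rnaseq
from coculture.synthdata import (
    PlantedDE,
    PlantedFeature,
    PlantedTruth,
    SyntheticDesign,
    gen_genomes,
    gen_peaktable,
)


@pytest.fixture(scope="session")
def design4():
    return SyntheticDesign(strains=["A", "B", "C", "D"], days=[2], replicates=2, seed=11)


@pytest.fixture(scope="session")
def design2():
    return SyntheticDesign(strains=["A", "C"], days=[2, 4], replicates=3, seed=5)


@pytest.fixture(scope="session")
def genomes4(design4):
    return gen_genomes(design4, genome_len=15_000, n_genes=10, shared_fraction=0.0)


@pytest.fixture(scope="session")
def genomes_shared(design4):
    return gen_genomes(design4, genome_len=15_000, n_genes=10, shared_fraction=0.4)


@pytest.fixture(scope="session")
def index4(genomes4):
    return rnaseq.build_index(genomes4, k=21)


@pytest.fixture(scope="session")
def index_shared(genomes_shared):
    return rnaseq.build_index(genomes_shared, k=21)


@pytest.fixture(scope="session")
def planted_truth2():
    truth = PlantedTruth()
    truth.producer_features["F0000"] = PlantedFeature("A", "C", 3.0, diffusible=False)
    truth.producer_features["F0001"] = PlantedFeature("C", None, 4.0, diffusible=True)
    truth.de_genes["A_g0000"] = PlantedDE("A", "C", (2, 4), 2.0)
    return truth


@pytest.fixture(scope="session")
def peaktable2(design2, planted_truth2):
    return gen_peaktable(
        design2, planted_truth2, n_features=80, drift_slope=0.2,
        missing_rate=0.05, seed=5,
    )


def brute_force_bh(p):
    """Independent step-up oracle: textbook definition, O(m^2)-naive."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
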
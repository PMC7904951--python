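import numpy as np
import pandas as pd
import pytest

from ripscreen import CountMatrix, SampleMeta, SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A 500-gene bundle, small enough for per-module tests."""
    return simulate_bundle(SimulationConfig(n_genes=500, depth=200_000, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_count_matrix(values, gene_ids=None, sample_ids=None, tissue="gonad",
                      genotype="wild_type"):
    """Small helper building a valid CountMatrix from a 2-D array."""
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    metas = [
        SampleMeta(sid, tissue, genotype, 25.0, i + 1)
        for i, sid in enumerate(sample_ids)
    ]
    return CountMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), metas)
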
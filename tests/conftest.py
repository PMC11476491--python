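import numpy as np
import pandas as pd
import pytest

from rescueseq.io import CountMatrix
from rescueseq.simdata import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated dataset shared across tests."""
    cm, truth = simulate_counts(SimConfig(n_genes=1000, seed=42))
    return cm, truth


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count matrix: 3 genes, two 2-replicate arms."""
    counts = pd.DataFrame(
        {
            "A_1": [10, 20, 30],
            "A_2": [12, 18, 33],
            "B_1": [20, 40, 60],
            "B_2": [22, 38, 57],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    arms = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    lengths = pd.Series([1000, 2000, 500], index=counts.index)
    return CountMatrix(counts=counts, arms=arms, gene_lengths=lengths)


def random_de_table(rng: np.random.Generator, n_genes: int) -> pd.DataFrame:
    """Random DE table: log2fc ~ N(0,1), fdr ~ U(0,1)."""
    idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    return pd.DataFrame(
        {
            "log2fc": rng.normal(0.0, 1.0, n_genes),
            "fdr": rng.uniform(0.0, 1.0, n_genes),
        },
        index=idx,
    )
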
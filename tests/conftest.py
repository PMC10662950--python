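import numpy as np
import pandas as pd
import pytest

from homoglia import SimulationConfig, log_normalize, simulate_two_species
from homoglia.containers import NormalizedMatrix
import scipy.sparse as sp


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated two-species pair shared across tests."""
    cfg = SimulationConfig(
        n_types=4, cells_per_type_per_species=60, n_genes=400, seed=7
    )
    return simulate_two_species(cfg)


@pytest.fixture(scope="session")
def small_norm(small_pair):
    counts_a, _, _ = small_pair
    return log_normalize(counts_a)


def dense_norm(values, cell_prefix="c", gene_prefix="g") -> NormalizedMatrix:
    """Wrap a dense array as a NormalizedMatrix for direct-formula tests."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return NormalizedMatrix(
        sp.csr_matrix(values),
        pd.Index([f"{cell_prefix}{i}" for i in range(n)]),
        pd.Index([f"{gene_prefix}{j}" for j in range(g)]),
    )
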
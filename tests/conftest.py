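import numpy as np
import pandas as pd
import pytest

from pantrx.datatypes import ExpressionMatrix
from pantrx.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset at generator defaults, shared across tests."""
    return simulate_population(SimConfig(seed=5))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced population for fast per-operation checks."""
    cfg = SimConfig(
        n_isolates=80,
        clade_sizes=(30, 20, 15, 10, 5),
        n_core_genes=120,
        n_accessory_genes=30,
        n_snps=80,
        n_cnvs=10,
        n_modules=3,
        module_sizes=(15, 15, 15),
        n_de_genes_per_clade=4,
        n_local_eqtl=5,
        n_distant_eqtl=5,
        seed=17,
    )
    return simulate_population(cfg)


def random_count_matrix(rng, n_genes=20, n_isolates=6, mean=200.0):
    counts = rng.poisson(mean, size=(n_genes, n_isolates))
    return ExpressionMatrix(
        pd.DataFrame(
            counts,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_isolates)],
        ),
        "raw_count",
    )
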
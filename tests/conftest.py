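import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from mammocci.datatypes import CountMatrix
from mammocci.preprocess import NormalizedMatrix, log_normalize
from mammocci.simulate import default_config, simulate_dataset
from mammocci.testing import random_cci_instance  # noqa: F401  (re-export for tests)


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulation (seed 0), shared across tests."""
    cfg = default_config(0)
    matrix, meta, truth = simulate_dataset(cfg)
    return {"config": cfg, "matrix": matrix, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def default_norm(default_sim):
    return log_normalize(default_sim["matrix"])


@pytest.fixture(scope="session")
def small_config():
    """A fast structural-test configuration (not used for recovery claims)."""
    return dataclasses.replace(
        default_config(0), n_cells_per_phase=120, n_genes=120
    ).validate()


def make_matrix(counts, genes=None, cells=None) -> CountMatrix:
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{j}" for j in range(counts.shape[1])]
    return CountMatrix(genes, cells, sp.csr_matrix(counts)).validate()


def make_norm_direct(values, counts, genes, cells, scale_factor=1e4) -> NormalizedMatrix:
    """Hand-built normalized matrix for tests that pin group means exactly."""
    return NormalizedMatrix(
        gene_symbols=list(genes),
        cell_ids=list(cells),
        values=sp.csr_matrix(np.asarray(values, dtype=float)),
        counts=sp.csr_matrix(np.asarray(counts)),
        scale_factor=scale_factor,
        dropped_cells=[],
    )


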
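"""Helpers for randomized verification of the scoring contracts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix
from .preprocess import NormalizedMatrix, log_normalize


def random_cci_instance(
    rng: np.random.Generator,
) -> tuple[NormalizedMatrix, pd.DataFrame, pd.DataFrame]:
    """A tiny random scoring instance: <=4 types, <=6 genes, <=60 cells.

    Used to compare :func:`mammocci.cci.score_cci` against the exhaustive
    oracle on inputs small enough for the oracle's nested loops.
    """
    n_genes = int(rng.integers(2, 7))
    n_cells = int(rng.integers(8, 61))
    n_types = int(rng.integers(1, 5))
    phases = ["virgin", "pregnancy"][: int(rng.integers(1, 3))]
    genes = [f"G{i}" for i in range(n_genes)]
    cells = [f"c{j}" for j in range(n_cells)]
    counts = rng.poisson(0.8, size=(n_genes, n_cells))
    counts[0, :] += 1  # avoid zero-total cells
    matrix = CountMatrix(genes, cells, sp.csr_matrix(counts)).validate()
    meta = pd.DataFrame(
        {
            "cell_id": cells,
            "phase": rng.choice(phases, n_cells),
            "cell_type": rng.choice([f"T{k}" for k in range(n_types)], n_cells),
        }
    )
    n_pairs = min(int(rng.integers(1, 7)), n_genes * (n_genes - 1))
    pairs = set()
    while len(pairs) < n_pairs:
        s, t = rng.choice(n_genes, 2, replace=False)
        pairs.add((genes[s], genes[t]))
    pair_df = pd.DataFrame(sorted(pairs), columns=["source_gene", "target_gene"])
    return log_normalize(matrix), meta, pair_df
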
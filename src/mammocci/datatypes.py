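"""Core in-memory containers shared across the pipeline.

The pipeline passes around three kinds of objects: a genes x cells count
matrix (``CountMatrix``), a per-cell metadata table (a pandas DataFrame with
a fixed schema, see :func:`validate_metadata`), and a directed
collagen -> collagen-binding interaction table (a DataFrame, see
:func:`validate_interactions`). Collagen families are keyed by the Roman
numerals used in the ECM literature ("I", "III", "IV", "V").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

PHASES: tuple[str, ...] = ("virgin", "pregnancy", "lactation", "involution")

CELL_TYPES: tuple[str, ...] = (
    "luminal epithelium",
    "basal epithelium",
    "stromal fibroblast",
    "T cell",
    "B cell",
    "myeloid cell",
    "endothelium",
)

IMMUNE_TYPES: frozenset[str] = frozenset({"T cell", "B cell", "myeloid cell"})

#: Default mapping from collagen family to mouse gene symbols. Families I and
#: III are the fibrillar collagens dominant in the mammary fat pad; IV is the
#: basement-membrane collagen; V is a minor fibrillar collagen. Membership of
#: the IV/V families is a configurable convention.
DEFAULT_COLLAGEN_CATALOG: dict[str, tuple[str, ...]] = {
    "I": ("Col1a1", "Col1a2"),
    "III": ("Col3a1",),
    "IV": ("Col4a1", "Col4a2"),
    "V": ("Col5a1", "Col5a2"),
}

#: Default collagen-binding partner genes and the collagen families each one
#: binds. Integrin beta-1 pairs broadly; DDRs and the alpha integrins are
#: restricted to the fibrillar/network families they are known to engage.
DEFAULT_BINDING_PARTNERS: dict[str, tuple[str, ...]] = {
    "Itgb1": ("I", "III", "IV", "V"),
    "Itga1": ("I", "IV"),
    "Itga2": ("I", "III"),
    "Ddr1": ("I", "IV"),
    "Ddr2": ("I", "III"),
    "Cd44": ("I", "IV"),
}

#: Marker genes used both by the simulator (planted cell-type programs) and
#: by the default annotation step.
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "luminal epithelium": ("Krt8", "Krt18", "Elf5"),
    "basal epithelium": ("Krt5", "Krt14", "Acta2"),
    "stromal fibroblast": ("Pdgfra", "Dpt", "Fbln1"),
    "T cell": ("Cd3e", "Cd3d", "Lck"),
    "B cell": ("Cd19", "Ms4a1", "Cd79a"),
    "myeloid cell": ("Lyz2", "Csf1r", "Itgam"),
    "endothelium": ("Pecam1", "Cdh5", "Kdr"),
}

#: Grouping of cell types for chord-diagram tables: epithelia / immune /
#: stroma (endothelium is grouped with stroma).
DEFAULT_GROUP_MAP: dict[str, str] = {
    "luminal epithelium": "epithelia",
    "basal epithelium": "epithelia",
    "stromal fibroblast": "stroma",
    "endothelium": "stroma",
    "T cell": "immune",
    "B cell": "immune",
    "myeloid cell": "immune",
}

METADATA_COLUMNS = ("cell_id", "phase", "cell_type", "cluster")
INTERACTION_COLUMNS = ("source_gene", "target_gene", "family")


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer expression counts.

    ``counts`` is stored sparse (CSR); axis 0 is genes, axis 1 is cells.
    """

    gene_symbols: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.gene_symbols = list(self.gene_symbols)
        self.cell_ids = list(self.cell_ids)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def validate(self) -> "CountMatrix":
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValidationError("duplicate gene symbols in count matrix")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids in count matrix")
        if self.counts.shape != (self.n_genes, self.n_cells):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{self.n_genes} genes x {self.n_cells} cells"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative entries in count matrix")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integral entries in count matrix")
        return self

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices for ``genes``; unknown symbols raise with the list."""
        lookup = {g: i for i, g in enumerate(self.gene_symbols)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)


def validate_metadata(
    meta: pd.DataFrame,
    matrix: CountMatrix | None = None,
    phases: Sequence[str] = PHASES,
) -> pd.DataFrame:
    """Check the per-cell metadata schema; optionally check pairing.

    Required columns: ``cell_id`` and ``phase``. ``cell_type`` / ``cluster``
    are optional until annotation has run. When ``matrix`` is given the
    cell ids must match the matrix's cell ids exactly (same set, any order).
    """
    for col in ("cell_id", "phase"):
        if col not in meta.columns:
            raise ValidationError(f"metadata missing required column {col!r}")
    if meta["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell ids in metadata")
    bad_phase = set(meta["phase"]) - set(phases)
    if bad_phase:
        raise ValidationError(f"unknown phase labels: {sorted(bad_phase)}")
    if matrix is not None and set(meta["cell_id"]) != set(matrix.cell_ids):
        raise ValidationError("metadata cell ids do not match matrix cell ids")
    return meta


def validate_interactions(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("source_gene", "target_gene"):
        if col not in table.columns:
            raise ValidationError(f"interaction table missing column {col!r}")
    if "family" not in table.columns:
        table = table.assign(family=pd.NA)
    if (table["source_gene"] == table["target_gene"]).any():
        raise ValidationError("interaction table contains self-pairs")
    if table.duplicated(["source_gene", "target_gene"]).any():
        raise ValidationError("duplicate (source, target) rows")
    return table[list(INTERACTION_COLUMNS)]


def catalog_genes(catalog: Mapping[str, Sequence[str]]) -> list[str]:
    """All gene symbols of a collagen catalog, in family order."""
    out: list[str] = []
    for fam in catalog:
        out.extend(catalog[fam])
    return out


def family_of_gene(catalog: Mapping[str, Sequence[str]]) -> dict[str, str]:
    return {g: fam for fam, genes in catalog.items() for g in genes}
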
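"""Readers and writers for the pipeline's on-disk formats.

Supported formats:

* MCA-style DGE text: tab-delimited genes x cells integer table, header row
  of cell ids (with or without a leading empty field for the gene column;
  the writer always emits the leading-empty-field form).
* MatrixMarket coordinate triplets plus ``genes.tsv`` / ``barcodes.tsv``
  sidecars (1-based indices, genes x cells).
* TSV for cell metadata and interaction pair tables.

Readers reject malformed input (ragged rows, non-integer counts, duplicate
symbols, out-of-bounds indices) with line-numbered errors rather than
coercing silently.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    CountMatrix,
    METADATA_COLUMNS,
    validate_interactions,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message carries the offending line when known."""


# ---------------------------------------------------------------------------
# DGE text
# ---------------------------------------------------------------------------

def read_dge(path: str | Path) -> CountMatrix:
    """Read an MCA-style tab-delimited DGE file."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}: empty file")
        header_fields = header.rstrip("\n").split("\t")
        gene_symbols: list[str] = []
        rows: list[list[int]] = []
        cell_ids: list[str] | None = None
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if cell_ids is None:
                # disambiguate the header dialect from the first data row
                if len(header_fields) == len(fields):
                    cell_ids = header_fields[1:]  # leading empty/gene-col field
                elif len(header_fields) == len(fields) - 1:
                    cell_ids = header_fields
                else:
                    raise ParseError(
                        f"{path}:{lineno}: row has {len(fields) - 1} values for "
                        f"{len(header_fields)} header fields"
                    )
            if len(fields) != len(cell_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(fields) - 1} values, "
                    f"expected {len(cell_ids)})"
                )
            gene = fields[0]
            values = []
            for v in fields[1:]:
                try:
                    values.append(int(v))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer count {v!r}"
                    ) from None
                if values[-1] < 0:
                    raise ParseError(f"{path}:{lineno}: negative count {v!r}")
            gene_symbols.append(gene)
            rows.append(values)
    if cell_ids is None:
        raise ParseError(f"{path}: no data rows")
    seen: set[str] = set()
    for i, g in enumerate(gene_symbols):
        if g in seen:
            raise ParseError(f"{path}:{i + 2}: duplicate gene symbol {g!r}")
        seen.add(g)
    if len(set(cell_ids)) != len(cell_ids):
        raise ParseError(f"{path}:1: duplicate cell ids in header")
    counts = sp.csr_matrix(np.asarray(rows, dtype=np.int64))
    return CountMatrix(gene_symbols, cell_ids, counts).validate()


def write_dge(matrix: CountMatrix, path: str | Path) -> None:
    """Write the canonical DGE form (leading empty header field)."""
    path = Path(path)
    dense = np.asarray(matrix.counts.todense(), dtype=np.int64)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(matrix.cell_ids) + "\n")
        for g, row in zip(matrix.gene_symbols, dense):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# MatrixMarket + sidecars
# ---------------------------------------------------------------------------

def read_mtx(directory: str | Path) -> CountMatrix:
    """Read ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` from a directory."""
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    try:
        mat = scipy.io.mmread(mtx_path)
    except (ValueError, OSError) as exc:
        raise ParseError(f"{mtx_path}: {exc}") from exc
    genes = (directory / "genes.tsv").read_text(encoding="utf-8").splitlines()
    barcodes = (directory / "barcodes.tsv").read_text(encoding="utf-8").splitlines()
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise ParseError(
            f"{mtx_path}: declared shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ParseError(f"{mtx_path}: non-integer values")
    return CountMatrix(genes, barcodes, mat.astype(np.int64)).validate()


def write_mtx(matrix: CountMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.counts.astype(np.int64))
    scipy.io.mmwrite(directory / "matrix.mtx", coo, field="integer")
    (directory / "genes.tsv").write_text(
        "".join(g + "\n" for g in matrix.gene_symbols), encoding="utf-8"
    )
    (directory / "barcodes.tsv").write_text(
        "".join(c + "\n" for c in matrix.cell_ids), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_interaction_table(
    path: str | Path,
    source_col: str | int = 0,
    target_col: str | int = 1,
    family_col: str | int | None = None,
) -> pd.DataFrame:
    """Read a directed gene-pair TSV; dedup and drop self-pairs (logged).

    Column mapping is configurable because interaction-list exports vary in
    schema; by default the first two columns are source and target.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: interaction table needs >= 2 columns")

    def _col(ref: str | int) -> pd.Series:
        return df.iloc[:, ref] if isinstance(ref, int) else df[ref]

    out = pd.DataFrame(
        {
            "source_gene": _col(source_col).astype(str),
            "target_gene": _col(target_col).astype(str),
        }
    )
    out["family"] = _col(family_col).astype(str) if family_col is not None else pd.NA
    n0 = len(out)
    out = out[out["source_gene"] != out["target_gene"]]
    n_self = n0 - len(out)
    if n_self:
        logger.warning("%s: dropped %d self-pair row(s)", path, n_self)
    n1 = len(out)
    out = out.drop_duplicates(["source_gene", "target_gene"]).reset_index(drop=True)
    if n1 - len(out):
        logger.warning("%s: dropped %d duplicate row(s)", path, n1 - len(out))
    if out.empty:
        logger.warning("%s: interaction table is empty", path)
    return validate_interactions(out)


def write_interaction_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_interactions(table).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    if "cluster" in meta.columns:
        meta["cluster"] = meta["cluster"].astype("Int64")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in meta.columns]
    meta[cols].to_csv(path, sep="\t", index=False)


def describe_file(path: str | Path) -> str:
    """Best-effort format/integrity report used by ``mammocci io validate``."""
    path = Path(path)
    if path.is_dir():
        m = read_mtx(path)
        return f"MTX directory: {m.n_genes} genes x {m.n_cells} cells, valid"
    head = path.open("r", encoding="utf-8").readline()
    if head.startswith("%%MatrixMarket"):
        return "bare MatrixMarket file (sidecars missing); place in a directory"
    first = head.rstrip("\n").split("\t")
    if first and first[0] in ("", "gene") or len(first) > 3:
        m = read_dge(path)
        return f"DGE text: {m.n_genes} genes x {m.n_cells} cells, valid"
    t = read_interaction_table(path)
    return f"interaction/metadata TSV: {len(t)} rows, valid"
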
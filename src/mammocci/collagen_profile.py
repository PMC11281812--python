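"""Per-(phase, cell type) collagen expression summaries and producer calls.

The qualitative claims of interest — which cell populations produce which
collagen family in which phase — are made operational as a dual-threshold
rule on per-group summaries: a (phase, type) population is called a producer
of a collagen family when at least one of the family's genes is expressed in
at least ``min_frac`` of the population's cells (raw count > 0) with mean
log-normalized expression at least ``min_mean``. Both thresholds are
inclusive and exposed on the CLI; "expressing" always means raw count > 0,
so the fraction is invariant to the normalization.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import IMMUNE_TYPES, ValidationError, family_of_gene
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_FRAC = 0.1
DEFAULT_MIN_MEAN = 0.25


def _group_cells(
    norm: NormalizedMatrix, meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    for col in ("cell_id", "phase", "cell_type"):
        if col not in meta.columns:
            raise ValidationError(f"metadata missing column {col!r}")
    meta = meta.set_index("cell_id").loc[norm.cell_ids].reset_index()
    groups: dict[tuple[str, str], np.ndarray] = {}
    for (phase, ctype), sub in meta.groupby(["phase", "cell_type"], sort=True):
        groups[(str(phase), str(ctype))] = sub.index.to_numpy()
    return meta, groups


def summarize_expression(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Mean expression and fraction expressing per (phase, cell type, gene).

    The grid covers every (phase, type) combination present in the metadata
    crossed with every requested gene; combinations with zero cells are
    omitted with a warning. ``frac_expressing`` counts raw counts > 0;
    ``mean_norm_expr`` averages log-normalized values.
    """
    gidx = norm.gene_index(genes)  # raises listing unknown genes
    meta, groups = _group_cells(norm, meta)
    phases = meta["phase"].unique()
    types = meta["cell_type"].unique()
    absent = [
        (p, t) for p in phases for t in types if (str(p), str(t)) not in groups
    ]
    if absent:
        warnings.warn(f"omitting empty (phase, type) groups: {absent}", stacklevel=2)
    vals = norm.values[gidx]
    nnz = norm.counts[gidx]
    rows = []
    for (phase, ctype), cols in groups.items():
        sub_vals = vals[:, cols]
        sub_nnz = nnz[:, cols]
        means = np.asarray(sub_vals.mean(axis=1)).ravel()
        fracs = np.asarray((sub_nnz > 0).sum(axis=1)).ravel() / cols.size
        for g, m, f in zip(genes, means, fracs):
            rows.append(
                {
                    "phase": phase,
                    "cell_type": ctype,
                    "gene": g,
                    "mean_norm_expr": float(m),
                    "frac_expressing": float(f),
                    "n_cells": int(cols.size),
                }
            )
    return pd.DataFrame(rows)


def call_producers(
    summary: pd.DataFrame,
    catalog: Mapping[str, Sequence[str]],
    min_frac: float = DEFAULT_MIN_FRAC,
    min_mean: float = DEFAULT_MIN_MEAN,
) -> pd.DataFrame:
    """Threshold the summary into per-(phase, type, family) producer calls.

    A row is a producer iff >= 1 family gene has ``frac_expressing >=
    min_frac`` and ``mean_norm_expr >= min_mean`` (both inclusive). The
    supporting genes of each call are listed comma-separated.
    """
    fam_of = family_of_gene(catalog)
    cat_genes = set(fam_of)
    have = set(summary["gene"])
    missing = sorted(cat_genes - have)
    if missing:
        raise ValidationError(f"summary is missing catalog genes: {missing}")
    sub = summary[summary["gene"].isin(cat_genes)].copy()
    sub["family"] = sub["gene"].map(fam_of)
    sub["passes"] = (sub["frac_expressing"] >= min_frac) & (
        sub["mean_norm_expr"] >= min_mean
    )
    rows = []
    for (phase, ctype, family), grp in sub.groupby(
        ["phase", "cell_type", "family"], sort=True
    ):
        supporting = sorted(grp.loc[grp["passes"], "gene"])
        rows.append(
            {
                "phase": phase,
                "cell_type": ctype,
                "family": family,
                "is_producer": bool(supporting),
                "supporting_genes": ",".join(supporting),
            }
        )
    return pd.DataFrame(rows)


def producer_blocks(calls: pd.DataFrame) -> frozenset:
    """The set of (phase, cell_type, family) triples called producers."""
    pos = calls[calls["is_producer"]]
    return frozenset(
        zip(pos["phase"], pos["cell_type"], pos["family"])
    )


def ectopic_report(
    calls: pd.DataFrame, immune_types: Iterable[str] = IMMUNE_TYPES
) -> pd.DataFrame:
    """Producer calls restricted to immune cell types (the ectopic program).

    Empty when no immune population passes the thresholds — in particular
    under the null simulation.
    """
    immune = set(immune_types)
    sub = calls[calls["is_producer"] & calls["cell_type"].isin(immune)]
    return (
        sub[["phase", "cell_type", "family"]]
        .sort_values(["phase", "cell_type", "family"])
        .reset_index(drop=True)
    )


def long_expression_table(
    norm: NormalizedMatrix, meta: pd.DataFrame, genes: Sequence[str]
) -> pd.DataFrame:
    """Violin-plot-ready long table: (phase, cell_type, gene, cell_id, value)."""
    gidx = norm.gene_index(genes)
    meta, _ = _group_cells(norm, meta)
    dense = np.asarray(norm.values[gidx].todense())
    frames = []
    for i, g in enumerate(genes):
        frames.append(
            pd.DataFrame(
                {
                    "phase": meta["phase"],
                    "cell_type": meta["cell_type"],
                    "gene": g,
                    "cell_id": meta["cell_id"],
                    "value": dense[i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
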
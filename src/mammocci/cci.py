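"""Directed collagen -> collagen-binding cell-cell interaction scoring.

Within each phase, every ordered pair of cell types (A, B) — including
A = B — is scored for every interaction pair (g_s -> g_t): the score is the
product of the mean log-normalized expression of the collagen gene g_s over
A's cells and of the binding gene g_t over B's cells. A row is emitted only
when both populations pass a fraction-expressing gate (raw count > 0 in at
least ``min_frac_source`` / ``min_frac_target`` of cells, and strictly more
than zero cells). Totals per phase and chord-diagram tables are plain sums
of the row scores, so every aggregate is additive by construction.

The product-of-means form is a declared convention (recorded in run
metadata); it is isolated in :func:`score_cci` so alternative statistics can
be swapped in. :func:`oracle_score_cci` recomputes the identical contract
with exhaustive Python loops and serves as the independent reference in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_GROUP_MAP,
    PHASES,
    ValidationError,
    catalog_genes,
    family_of_gene,
)
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

SCORE_FORMULA = "product_of_group_means"

SCORE_COLUMNS = (
    "phase",
    "source_type",
    "target_type",
    "source_gene",
    "target_gene",
    "score",
)


@dataclass(frozen=True)
class CCIPairGate:
    """Fraction-expressing gate applied to source and target populations."""

    min_frac_source: float = 0.1
    min_frac_target: float = 0.1

    def __post_init__(self) -> None:
        for name in ("min_frac_source", "min_frac_target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


def filter_collagen_pairs(
    interactions: pd.DataFrame, catalog: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Keep rows whose *source* gene is a catalog collagen; annotate family.

    Direction matters: a collagen appearing only in the target position does
    not make a row collagen-sourced, so it is dropped.
    """
    fam_of = family_of_gene(catalog)
    keep = interactions["source_gene"].isin(fam_of)
    out = interactions.loc[keep, ["source_gene", "target_gene"]].copy()
    out["family"] = out["source_gene"].map(fam_of)
    return out.reset_index(drop=True)


def _group_stats(
    norm: NormalizedMatrix, meta: pd.DataFrame, genes: list[str]
) -> tuple[dict, list[str], list[str]]:
    """Per-(phase, type) mean normalized expression and fraction expressing."""
    for col in ("cell_id", "phase", "cell_type"):
        if col not in meta.columns:
            raise ValidationError(f"metadata missing column {col!r}")
    if meta["cell_type"].isna().any() or meta["phase"].isna().any():
        raise ValidationError("metadata has cells without phase or cell_type")
    meta = meta.set_index("cell_id").loc[norm.cell_ids].reset_index()
    gidx = norm.gene_index(genes)
    vals = norm.values[gidx]
    cnts = norm.counts[gidx]
    stats: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (phase, ctype), sub in meta.groupby(["phase", "cell_type"], sort=True):
        cols = sub.index.to_numpy()
        mean = np.asarray(vals[:, cols].mean(axis=1)).ravel()
        frac = np.asarray((cnts[:, cols] > 0).sum(axis=1)).ravel() / cols.size
        stats[(str(phase), str(ctype))] = (mean, frac)
    phases = [str(p) for p in pd.unique(meta["phase"])]
    types = sorted(str(t) for t in meta["cell_type"].unique())
    return stats, phases, types


def score_cci(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    pairs: pd.DataFrame,
    gate: CCIPairGate = CCIPairGate(),
    include_self: bool = True,
) -> pd.DataFrame:
    """Score all (phase, source type, target type, gene pair) interactions.

    Pair genes absent from the matrix are skipped with a logged count. The
    output is sorted by (phase, source_type, target_type, source_gene,
    target_gene) and fully deterministic.
    """
    known = set(norm.gene_symbols)
    usable = pairs[
        pairs["source_gene"].isin(known) & pairs["target_gene"].isin(known)
    ]
    n_skip = len(pairs) - len(usable)
    if n_skip:
        logger.warning("skipping %d pair(s) with genes absent from matrix", n_skip)
    if usable.empty:
        return pd.DataFrame(columns=list(SCORE_COLUMNS))
    genes = sorted(set(usable["source_gene"]) | set(usable["target_gene"]))
    pos = {g: i for i, g in enumerate(genes)}
    stats, phases, types = _group_stats(norm, meta, genes)

    pair_rows = sorted(
        zip(usable["source_gene"], usable["target_gene"])
    )
    rows = []
    for phase in phases:
        for src_t in types:
            if (phase, src_t) not in stats:
                continue
            mean_s, frac_s = stats[(phase, src_t)]
            for tgt_t in types:
                if (phase, tgt_t) not in stats:
                    continue
                if not include_self and src_t == tgt_t:
                    continue
                mean_t, frac_t = stats[(phase, tgt_t)]
                for g_s, g_t in pair_rows:
                    fs, ft = frac_s[pos[g_s]], frac_t[pos[g_t]]
                    if fs < gate.min_frac_source or ft < gate.min_frac_target:
                        continue
                    if fs == 0.0 or ft == 0.0:  # unexpressed cannot interact
                        continue
                    rows.append(
                        (
                            phase,
                            src_t,
                            tgt_t,
                            g_s,
                            g_t,
                            float(mean_s[pos[g_s]] * mean_t[pos[g_t]]),
                        )
                    )
    out = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    return out.sort_values(list(SCORE_COLUMNS[:5])).reset_index(drop=True)


def oracle_score_cci(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    pairs: pd.DataFrame,
    gate: CCIPairGate = CCIPairGate(),
    include_self: bool = True,
) -> pd.DataFrame:
    """Reference implementation: exhaustive loops, no vectorization.

    Same contract as :func:`score_cci`; intended for small instances only.
    """
    for col in ("cell_id", "phase", "cell_type"):
        if col not in meta.columns:
            raise ValidationError(f"metadata missing column {col!r}")
    if meta["cell_type"].isna().any() or meta["phase"].isna().any():
        raise ValidationError("metadata has cells without phase or cell_type")
    phase_of = dict(zip(meta["cell_id"], meta["phase"]))
    type_of = dict(zip(meta["cell_id"], meta["cell_type"]))
    values = norm.values.toarray()
    counts = norm.counts.toarray()
    gene_row = {g: i for i, g in enumerate(norm.gene_symbols)}

    known = set(norm.gene_symbols)
    pair_list = sorted(
        (s, t)
        for s, t in zip(pairs["source_gene"], pairs["target_gene"])
        if s in known and t in known
    )
    phases = list(dict.fromkeys(str(phase_of[c]) for c in norm.cell_ids))
    types = sorted({str(type_of[c]) for c in norm.cell_ids})

    def group_mean_frac(phase: str, ctype: str, gene: str):
        members = [
            j
            for j, c in enumerate(norm.cell_ids)
            if str(phase_of[c]) == phase and str(type_of[c]) == ctype
        ]
        if not members:
            return None
        i = gene_row[gene]
        total = 0.0
        n_expr = 0
        for j in members:
            total += values[i, j]
            if counts[i, j] > 0:
                n_expr += 1
        return total / len(members), n_expr / len(members)

    rows = []
    for phase in phases:
        for src_t in types:
            for tgt_t in types:
                if not include_self and src_t == tgt_t:
                    continue
                for g_s, g_t in pair_list:
                    src = group_mean_frac(phase, src_t, g_s)
                    tgt = group_mean_frac(phase, tgt_t, g_t)
                    if src is None or tgt is None:
                        continue
                    mean_s, frac_s = src
                    mean_t, frac_t = tgt
                    if frac_s < gate.min_frac_source or frac_t < gate.min_frac_target:
                        continue
                    if frac_s == 0.0 or frac_t == 0.0:
                        continue
                    rows.append(
                        (phase, src_t, tgt_t, g_s, g_t, mean_s * mean_t)
                    )
    out = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    return out.sort_values(list(SCORE_COLUMNS[:5])).reset_index(drop=True)


def total_cci(
    scores: pd.DataFrame, phases: Sequence[str] = PHASES
) -> pd.Series:
    """Sum of all interaction scores per phase (the bar-plot quantity).

    Phases with no rows report 0 with a warning.
    """
    sums = scores.groupby("phase")["score"].sum() if len(scores) else pd.Series(dtype=float)
    out = pd.Series({p: float(sums.get(p, 0.0)) for p in phases}, name="total_cci")
    missing = [p for p in phases if p not in sums.index]
    if missing:
        logger.warning("no interaction rows for phase(s) %s; reporting 0", missing)
    return out


def circos_table(
    scores: pd.DataFrame, group_map: Mapping[str, str] = DEFAULT_GROUP_MAP
) -> pd.DataFrame:
    """Chord-diagram input: per (phase, source type, target type) sums.

    Every cell type must be mapped to a group (epithelia / immune / stroma
    by default); the group annotations are carried alongside for coloring.
    """
    if scores.empty:
        return pd.DataFrame(
            columns=[
                "phase",
                "source_type",
                "source_group",
                "target_type",
                "target_group",
                "score",
            ]
        )
    unmapped = sorted(
        (set(scores["source_type"]) | set(scores["target_type"])) - set(group_map)
    )
    if unmapped:
        raise ValidationError(f"cell types missing from group map: {unmapped}")
    agg = (
        scores.groupby(["phase", "source_type", "target_type"], sort=True)["score"]
        .sum()
        .reset_index()
    )
    agg.insert(2, "source_group", agg["source_type"].map(group_map))
    agg.insert(4, "target_group", agg["target_type"].map(group_map))
    return agg
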
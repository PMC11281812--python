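"""Synthetic scRNA-seq generator with planted collagen programs.

The generator emulates a drop-seq style genes x cells count matrix over the
four mammary-gland phases (virgin, pregnancy, lactation, involution) with a
known ("planted") collagen expression structure, so every downstream stage —
normalization, annotation, producer calling, cell-cell interaction scoring —
can be tested against a ground truth:

* stromal fibroblasts produce type I/III collagen in every phase;
* the three immune types (T, B, myeloid) additionally produce type I/III
  collagen, but only in the pregnancy phase (the "ectopic" program);
* type V collagen is produced only by pregnancy-phase fibroblasts;
* type IV is fibroblast-restricted in all phases, with a reduced program in
  lactation;
* fibroblast I/III programs are boosted in involution, reflecting the heavy
  ECM remodeling of that phase, so that total interaction mass is ordered
  pregnancy > involution > virgin/lactation.

Counts are negative binomial (gamma-Poisson) with a shared dispersion;
per-cell depth is log-normal; background genes carry log-normal baseline
abundances so library sizes are dominated by a realistic heavy tail. An
"on" (phase, type, gene) block elevates the NB mean by ``program_fold`` in a
random ``expressing_fraction_on`` subset of the block's cells, which makes
fraction-expressing gates downstream meaningful (sparse, dot-plot-like
signal rather than a uniform shift).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (
    CELL_TYPES,
    DEFAULT_BINDING_PARTNERS,
    DEFAULT_COLLAGEN_CATALOG,
    DEFAULT_MARKERS,
    IMMUNE_TYPES,
    PHASES,
    CountMatrix,
    ValidationError,
    catalog_genes,
    validate_interactions,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A simulation config violates one of its invariants."""


#: Cell-type composition shared by all phases (the atlas does not report a
#: per-phase breakdown, so a single realistic mixture is used throughout).
DEFAULT_COMPOSITION: dict[str, float] = {
    "luminal epithelium": 0.22,
    "basal epithelium": 0.10,
    "stromal fibroblast": 0.20,
    "T cell": 0.16,
    "B cell": 0.10,
    "myeloid cell": 0.12,
    "endothelium": 0.10,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    All means are per-gene NB means before per-cell depth scaling;
    ``dispersion`` is the NB size parameter (variance = mu + mu^2/size).
    """

    n_cells_per_phase: int = 1500
    phases: tuple[str, ...] = PHASES
    cell_types: tuple[str, ...] = CELL_TYPES
    composition: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    n_genes: int = 1000
    base_mean: float = 0.03
    dispersion: float = 2.0
    program_fold: float = 20.0
    marker_fold: float = 40.0
    binding_fold: float = 12.0
    background_lognorm_sigma: float = 2.0
    type_de_fraction: float = 0.1
    type_de_sigma: float = 1.0
    lactation_col4_reduction: float = 0.6
    involution_fold_boost: float = 2.0
    library_size_mean: float = 1.0
    library_size_sd: float = 0.35
    expressing_fraction_on: float = 0.6
    seed: int = 0
    collagen_catalog: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COLLAGEN_CATALOG)
    )
    binding_partners: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BINDING_PARTNERS)
    )
    markers: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )

    def __post_init__(self) -> None:
        if not self.composition:
            self.composition = {p: dict(DEFAULT_COMPOSITION) for p in self.phases}

    # -- derived gene sets -------------------------------------------------
    @property
    def collagen_genes(self) -> list[str]:
        return catalog_genes(self.collagen_catalog)

    @property
    def binding_genes(self) -> list[str]:
        return list(self.binding_partners)

    @property
    def marker_genes(self) -> list[str]:
        return [g for t in self.cell_types for g in self.markers.get(t, ())]

    @property
    def n_background(self) -> int:
        named = len(self.collagen_genes) + len(self.binding_genes) + len(self.marker_genes)
        return self.n_genes - named

    def validate(self) -> "SimulationConfig":
        if self.n_cells_per_phase <= 0:
            raise ConfigurationError("n_cells_per_phase must be positive")
        for name in ("base_mean", "dispersion", "library_size_mean", "library_size_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.program_fold < 1:
            raise ConfigurationError("program_fold must be >= 1")
        if not (0 < self.expressing_fraction_on <= 1):
            raise ConfigurationError("expressing_fraction_on must be in (0, 1]")
        if not (0 < self.lactation_col4_reduction < 1):
            raise ConfigurationError("lactation_col4_reduction must be in (0, 1)")
        if not (0 <= self.type_de_fraction <= 1):
            raise ConfigurationError("type_de_fraction must be in [0, 1]")
        if self.type_de_sigma < 0:
            raise ConfigurationError("type_de_sigma must be non-negative")
        for phase in self.phases:
            props = self.composition.get(phase)
            if props is None:
                raise ConfigurationError(f"no composition for phase {phase!r}")
            if set(props) != set(self.cell_types):
                raise ConfigurationError(
                    f"composition for phase {phase!r} does not cover all cell types"
                )
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"composition for phase {phase!r} sums to {total!r}, not 1"
                )
        sets = [set(self.collagen_genes), set(self.binding_genes), set(self.marker_genes)]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ConfigurationError(
                        f"gene symbol lists overlap: {sorted(overlap)}"
                    )
        if self.n_background < 1:
            raise ConfigurationError(
                "n_genes too small for collagen + binding + marker genes"
            )
        return self


@dataclass(frozen=True)
class GroundTruth:
    """The planted structure: true labels, producer blocks, expected ordering."""

    cell_type_of_cell: Mapping[str, str]
    producer_blocks: frozenset  # of (phase, cell_type, family)
    expected_total_cci_order: tuple[str, ...]


def default_config(seed: int = 0) -> SimulationConfig:
    """Default four-phase, seven-type configuration (6000 cells total)."""
    return SimulationConfig(seed=seed).validate()


def planted_producer_blocks(config: SimulationConfig) -> frozenset:
    """The (phase, cell_type, family) blocks switched on by the simulator.

    Empty under the null model (``program_fold == 1``), where no block is
    distinguishable from background.
    """
    if config.program_fold == 1:
        return frozenset()
    blocks: set[tuple[str, str, str]] = set()
    for phase in config.phases:
        blocks.add((phase, "stromal fibroblast", "I"))
        blocks.add((phase, "stromal fibroblast", "III"))
        blocks.add((phase, "stromal fibroblast", "IV"))
    if "pregnancy" in config.phases:
        blocks.add(("pregnancy", "stromal fibroblast", "V"))
        for t in IMMUNE_TYPES:
            if t in config.cell_types:
                blocks.add(("pregnancy", t, "I"))
                blocks.add(("pregnancy", t, "III"))
    return frozenset(blocks)


def _block_fold(config: SimulationConfig, phase: str, cell_type: str, family: str) -> float:
    fold = config.program_fold
    if family == "IV" and phase == "lactation":
        fold *= config.lactation_col4_reduction
    if family in ("I", "III") and phase == "involution" and cell_type == "stromal fibroblast":
        fold *= config.involution_fold_boost
    return fold


def _allocate_counts(n: int, props: Mapping[str, float], order: Sequence[str]) -> dict[str, int]:
    # largest-remainder rounding so per-phase totals are exact
    raw = {t: n * props[t] for t in order}
    counts = {t: int(np.floor(raw[t])) for t in order}
    short = n - sum(counts.values())
    by_frac = sorted(order, key=lambda t: (-(raw[t] - counts[t]), t))
    for t in by_frac[:short]:
        counts[t] += 1
    return counts


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a full synthetic dataset; deterministic for a fixed seed.

    Returns the count matrix, per-cell metadata (true phase and type labels,
    no cluster assignment) and the ground truth of the planted structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    collagen = config.collagen_genes
    binding = config.binding_genes
    markers = config.marker_genes
    n_bg = config.n_background
    background = [f"Bg{i + 1:04d}" for i in range(n_bg)]
    genes = collagen + binding + markers + background
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # cell layout: phases in order, types in declared order within each phase
    cell_ids: list[str] = []
    cell_phase: list[str] = []
    cell_type: list[str] = []
    for phase in config.phases:
        alloc = _allocate_counts(
            config.n_cells_per_phase, config.composition[phase], config.cell_types
        )
        for t in config.cell_types:
            for _ in range(alloc[t]):
                cell_ids.append(f"{phase}_{len(cell_ids) + 1:05d}")
                cell_phase.append(phase)
                cell_type.append(t)
    n_cells = len(cell_ids)
    phase_arr = np.array(cell_phase)
    type_arr = np.array(cell_type)

    # per-gene relative abundance: heavy-tailed background, elevated binding
    rel = np.ones(n_genes)
    for g in binding:
        rel[gene_idx[g]] = config.binding_fold
    rel[n_genes - n_bg :] = rng.lognormal(
        mean=0.0, sigma=config.background_lognorm_sigma, size=n_bg
    )
    depth = rng.lognormal(
        mean=np.log(config.library_size_mean), sigma=config.library_size_sd, size=n_cells
    )

    fold = np.ones((n_genes, n_cells))
    # per-type transcriptional programs: lognormal DE factors on a random
    # subset of background genes, shared across phases (splatter-style group
    # structure; real cell types differ across broad programs, not just
    # their canonical markers)
    bg_start = n_genes - n_bg
    for t in config.cell_types:
        de_mask = rng.random(n_bg) < config.type_de_fraction
        de_factors = rng.lognormal(mean=0.0, sigma=config.type_de_sigma, size=int(de_mask.sum()))
        cols = np.flatnonzero(type_arr == t)
        de_rows = bg_start + np.flatnonzero(de_mask)
        fold[np.ix_(de_rows, cols)] = de_factors[:, None]
    # marker programs: on for the whole population of their own type
    for t in config.cell_types:
        cols = np.flatnonzero(type_arr == t)
        for g in config.markers.get(t, ()):
            fold[gene_idx[g], cols] = config.marker_fold
    # planted collagen programs: sparse within-block activation
    blocks = planted_producer_blocks(config)
    for phase in config.phases:
        for t in config.cell_types:
            for family in config.collagen_catalog:
                if (phase, t, family) not in blocks:
                    continue
                cols = np.flatnonzero((phase_arr == phase) & (type_arr == t))
                eff = _block_fold(config, phase, t, family)
                for g in config.collagen_catalog[family]:
                    on = cols[rng.random(cols.size) < config.expressing_fraction_on]
                    fold[gene_idx[g], on] = eff

    mu = config.base_mean * rel[:, None] * fold * depth[None, :]
    lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
    counts = rng.poisson(lam).astype(np.int32)

    matrix = CountMatrix(genes, cell_ids, sp.csr_matrix(counts)).validate()
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "phase": cell_phase,
            "cell_type": cell_type,
            "cluster": pd.array([pd.NA] * n_cells, dtype="Int64"),
        }
    )
    order = (
        ("pregnancy", "involution", "virgin", "lactation")
        if config.program_fold > 1
        else ()
    )
    truth = GroundTruth(
        cell_type_of_cell=dict(zip(cell_ids, cell_type)),
        producer_blocks=blocks,
        expected_total_cci_order=order,
    )
    return matrix, meta, truth


def build_interaction_table(
    catalog: Mapping[str, Sequence[str]],
    binding_genes: Sequence[str],
    partner_families: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Directed collagen -> binding-gene pairs, restricted by family.

    Every row points from a collagen gene (source) to a collagen-binding
    gene (target). ``partner_families`` maps each binding gene to the
    collagen families it engages; by default every binding gene pairs with
    every family.
    """
    col_genes = set(catalog_genes(catalog))
    overlap = col_genes & set(binding_genes)
    if overlap:
        raise ValidationError(
            f"binding genes overlap collagen catalog: {sorted(overlap)}"
        )
    if partner_families is None:
        partner_families = {b: tuple(catalog) for b in binding_genes}
    rows = []
    for family, sources in catalog.items():
        for src in sources:
            for tgt in binding_genes:
                if family in partner_families.get(tgt, ()):
                    rows.append((src, tgt, family))
    table = pd.DataFrame(rows, columns=["source_gene", "target_gene", "family"])
    return validate_interactions(table)


def default_interaction_table(config: SimulationConfig | None = None) -> pd.DataFrame:
    config = config or default_config()
    return build_interaction_table(
        config.collagen_catalog, config.binding_genes, config.binding_partners
    )


def null_config(seed: int = 0) -> SimulationConfig:
    """Null model: no planted collagen programs (fold 1)."""
    return replace(default_config(seed), program_fold=1.0)
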
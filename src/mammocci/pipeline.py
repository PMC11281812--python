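"""End-to-end orchestration: simulate -> preprocess -> profile -> CCI.

A single :class:`RunConfig` drives the whole pipeline; every stage's output
is written to the run directory together with a provenance file (all
parameters, seed, score formula, package version) so a rerun with the same
config reproduces every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cci import (
    CCIPairGate,
    SCORE_FORMULA,
    circos_table,
    filter_collagen_pairs,
    score_cci,
    total_cci,
)
from .collagen_profile import (
    DEFAULT_MIN_FRAC,
    DEFAULT_MIN_MEAN,
    call_producers,
    ectopic_report,
    producer_blocks,
    summarize_expression,
)
from .datatypes import (
    DEFAULT_GROUP_MAP,
    DEFAULT_MARKERS,
    ValidationError,
    validate_metadata,
)
from .io_matrix import (
    read_dge,
    read_interaction_table,
    read_metadata,
    write_dge,
    write_interaction_table,
    write_metadata,
    write_mtx,
)
from .preprocess import DEFAULT_SCALE_FACTOR, annotate, log_normalize
from .simulate import (
    SimulationConfig,
    default_interaction_table,
    simulate_dataset,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (generate data) or ``inputs`` (paths to a
    DGE/MTX matrix, metadata TSV and interaction TSV) must be set. When the
    metadata already carries cell types, set ``annotate_cells`` to False to
    bypass clustering/annotation.
    """

    outdir: str = "results/run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: Mapping[str, str] | None = None
    annotate_cells: bool = True
    scale_factor: float = DEFAULT_SCALE_FACTOR
    n_pcs: int = 20
    n_neighbors: int = 15
    resolution: float = 1.0
    min_frac: float = DEFAULT_MIN_FRAC
    min_mean: float = DEFAULT_MIN_MEAN
    gate_source: float = 0.1
    gate_target: float = 0.1
    include_self: bool = True

    def validate(self) -> "RunConfig":
        if (self.simulation is None) == (self.inputs is None):
            raise ValidationError(
                "exactly one of simulation config or input paths must be set"
            )
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulation"})
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if cfg.simulation is not None:
            cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        return cfg.validate()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # propagate with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage, write all outputs under ``config.outdir``.

    Returns the run report (also written as ``report.yaml``): producer
    calls vs planted truth when a ground truth exists, the ectopic report,
    per-phase CCI totals and their ordering.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        matrix, meta, truth = _stage("simulate")(simulate_dataset, sim)
        pairs = default_interaction_table(sim)
        catalog = dict(sim.collagen_catalog)
        markers = dict(sim.markers)
        _stage("write-inputs")(write_dge, matrix, outdir / "counts.dge.txt")
        _stage("write-inputs")(write_mtx, matrix, outdir / "counts_mtx")
        write_interaction_table(pairs, outdir / "interactions.tsv")
    else:
        paths = dict(config.inputs)
        matrix = _stage("read-counts")(read_dge, paths["counts"])
        meta = _stage("read-metadata")(read_metadata, paths["metadata"])
        pairs = _stage("read-interactions")(
            read_interaction_table, paths["interactions"]
        )
        from .datatypes import DEFAULT_COLLAGEN_CATALOG

        catalog = dict(DEFAULT_COLLAGEN_CATALOG)
        markers = dict(DEFAULT_MARKERS)
    validate_metadata(meta, matrix)

    # preprocess
    if config.annotate_cells:
        norm, cells, cluster_report = _stage("preprocess")(
            annotate,
            matrix,
            markers,
            scale_factor=config.scale_factor,
            n_pcs=config.n_pcs,
            n_neighbors=config.n_neighbors,
            resolution=config.resolution,
            seed=config.seed,
        )
        meta = meta.drop(columns=["cell_type", "cluster"], errors="ignore").merge(
            cells, on="cell_id", how="inner"
        )
        cluster_report.to_csv(outdir / "cluster_report.tsv", sep="\t", index=False)
    else:
        if "cell_type" not in meta.columns or meta["cell_type"].isna().any():
            raise PipelineError(
                "stage 'preprocess' failed: annotate_cells is off but metadata "
                "lacks cell_type labels"
            )
        norm = _stage("preprocess")(log_normalize, matrix, config.scale_factor)
        meta = meta[meta["cell_id"].isin(set(norm.cell_ids))]
    write_metadata(meta, outdir / "metadata.tsv")

    # collagen profile
    from .datatypes import catalog_genes

    genes = catalog_genes(catalog)
    summary = _stage("profile")(summarize_expression, norm, meta, genes)
    calls = _stage("profile")(
        call_producers, summary, catalog, config.min_frac, config.min_mean
    )
    ectopic = ectopic_report(calls)
    summary.to_csv(outdir / "expression_summary.tsv", sep="\t", index=False)
    calls.to_csv(outdir / "producer_calls.tsv", sep="\t", index=False)
    ectopic.to_csv(outdir / "ectopic_report.tsv", sep="\t", index=False)

    # CCI
    gate = CCIPairGate(config.gate_source, config.gate_target)
    col_pairs = filter_collagen_pairs(pairs, catalog)
    scores = _stage("cci")(
        score_cci, norm, meta, col_pairs, gate, config.include_self
    )
    totals = total_cci(scores)
    chord = circos_table(scores, DEFAULT_GROUP_MAP)
    scores.to_csv(outdir / "cci_scores.tsv", sep="\t", index=False)
    chord.to_csv(outdir / "cci_chord.tsv", sep="\t", index=False)
    totals.rename_axis("phase").reset_index().to_csv(
        outdir / "cci_totals.tsv", sep="\t", index=False
    )

    ordering = list(totals.sort_values(ascending=False).index)
    report: dict[str, Any] = {
        "n_cells": int(matrix.n_cells),
        "n_genes": int(matrix.n_genes),
        "producer_calls": int(calls["is_producer"].sum()),
        "ectopic_calls": [
            [str(r.phase), str(r.cell_type), str(r.family)]
            for r in ectopic.itertuples()
        ],
        "cci_totals": {p: float(v) for p, v in totals.items()},
        "cci_total_ordering": ordering,
    }
    if truth is not None:
        called = producer_blocks(calls)
        planted = truth.producer_blocks
        report["producer_recovery"] = {
            "n_planted": len(planted),
            "n_called": len(called),
            "n_missed": len(planted - called),
            "n_spurious": len(called - planted),
            "exact": called == planted,
        }
        report["expected_total_cci_order"] = list(truth.expected_total_cci_order)

    provenance = {
        "tool": "mammocci",
        "version": __version__,
        "seed": config.seed,
        "score_formula": SCORE_FORMULA,
        "log_base": "natural",
        "parameters": _serializable(config),
    }
    (outdir / "provenance.yaml").write_text(
        yaml.safe_dump(provenance, sort_keys=True), encoding="utf-8"
    )
    (outdir / "report.yaml").write_text(
        yaml.safe_dump(report, sort_keys=True), encoding="utf-8"
    )
    return report


def _serializable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _serializable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Mapping):
        return {str(k): _serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def report_hash(outdir: str | Path) -> str:
    """SHA-256 over all run outputs; equal hashes mean byte-identical runs."""
    outdir = Path(outdir)
    h = hashlib.sha256()
    for p in sorted(outdir.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(outdir).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()
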
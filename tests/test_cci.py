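"""CCI scoring: direction, gating, oracle equivalence, additivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammocci.cci import (
    CCIPairGate,
    circos_table,
    filter_collagen_pairs,
    oracle_score_cci,
    score_cci,
    total_cci,
)
from mammocci.datatypes import (
    DEFAULT_COLLAGEN_CATALOG,
    DEFAULT_GROUP_MAP,
    PHASES,
    ValidationError,
)
from mammocci.preprocess import log_normalize
from mammocci.simulate import default_interaction_table

from conftest import make_matrix, make_norm_direct, random_cci_instance


class TestFilterCollagenPairs:
    def test_no_collagen_sources_empty(self):
        t = pd.DataFrame({"source_gene": ["Gapdh"], "target_gene": ["Itgb1"]})
        assert filter_collagen_pairs(t, DEFAULT_COLLAGEN_CATALOG).empty

    def test_mixed_table_keeps_catalog_sources_with_family(self):
        t = pd.DataFrame(
            {
                "source_gene": ["Col1a1", "Gapdh", "Col3a1", "Actb", "Eln"],
                "target_gene": ["Itgb1"] * 5,
            }
        )
        out = filter_collagen_pairs(t, DEFAULT_COLLAGEN_CATALOG)
        assert list(out["source_gene"]) == ["Col1a1", "Col3a1"]
        assert list(out["family"]) == ["I", "III"]

    def test_collagen_in_target_position_excluded(self):
        # direction matters: scores flow from collagens to binding proteins
        t = pd.DataFrame({"source_gene": ["Itgb1"], "target_gene": ["Col1a1"]})
        assert filter_collagen_pairs(t, DEFAULT_COLLAGEN_CATALOG).empty


def _two_type_instance():
    """Two types, one pair, hand-set group means: A=2.0, B=0.5 -> score 1.0."""
    genes = ["Col1a1", "Itgb1"]
    cells = ["a1", "a2", "b1", "b2"]
    values = np.array(
        [
            [2.0, 2.0, 0.0, 0.0],  # Col1a1: mean 2.0 in A
            [0.0, 0.0, 0.5, 0.5],  # Itgb1: mean 0.5 in B
        ]
    )
    counts = (values > 0).astype(int)
    norm = make_norm_direct(values, counts, genes, cells)
    meta = pd.DataFrame(
        {
            "cell_id": cells,
            "phase": ["virgin"] * 4,
            "cell_type": ["A", "A", "B", "B"],
        }
    )
    pairs = pd.DataFrame({"source_gene": ["Col1a1"], "target_gene": ["Itgb1"]})
    return norm, meta, pairs


class TestScoreCCI:
    def test_hand_computed_product(self):
        norm, meta, pairs = _two_type_instance()
        scores = score_cci(norm, meta, pairs, CCIPairGate(0.1, 0.1))
        row = scores[(scores.source_type == "A") & (scores.target_type == "B")]
        assert len(row) == 1
        assert row.iloc[0]["score"] == pytest.approx(1.0)

    def test_unexpressed_source_emits_no_row(self):
        norm, meta, pairs = _two_type_instance()
        scores = score_cci(norm, meta, pairs, CCIPairGate(0.0, 0.0))
        # Col1a1 is never expressed in B cells: no (B, *) source rows at all
        assert (scores["source_type"] == "B").sum() == 0

    def test_self_interactions_can_be_excluded(self):
        norm, meta, pairs = _two_type_instance()
        with_self = score_cci(norm, meta, pairs, CCIPairGate(0.0, 0.0), include_self=True)
        without = score_cci(norm, meta, pairs, CCIPairGate(0.0, 0.0), include_self=False)
        assert len(with_self) >= len(without)
        assert (without["source_type"] == without["target_type"]).sum() == 0

    def test_missing_pair_genes_skipped(self, default_sim, default_norm):
        pairs = pd.DataFrame(
            {"source_gene": ["Col1a1", "NotInMatrix"], "target_gene": ["Itgb1", "Itgb1"]}
        )
        scores = score_cci(default_norm, default_sim["meta"], pairs)
        assert set(scores["source_gene"]) == {"Col1a1"}

    def test_cells_without_labels_rejected(self):
        norm, meta, pairs = _two_type_instance()
        meta = meta.copy()
        meta.loc[0, "cell_type"] = None
        with pytest.raises(ValidationError):
            score_cci(norm, meta, pairs)

    def test_permuting_cell_order_leaves_scores_unchanged(self):
        rng = np.random.default_rng(5)
        norm, meta, pairs = random_cci_instance(rng)
        s1 = score_cci(norm, meta, pairs)
        s2 = score_cci(norm, meta.sample(frac=1, random_state=1), pairs)
        pd.testing.assert_frame_equal(s1, s2)

    def test_source_monotonicity_in_counts(self):
        """Raising a gated-in source gene's count never lowers its scores."""
        norm, meta, pairs = _two_type_instance()
        bumped = make_norm_direct(
            norm.values.toarray() + np.array([[0.5, 0, 0, 0], [0, 0, 0, 0]]),
            norm.counts.toarray(),
            norm.gene_symbols,
            norm.cell_ids,
        )
        base = score_cci(norm, meta, pairs, CCIPairGate(0.1, 0.1))
        more = score_cci(bumped, meta, pairs, CCIPairGate(0.1, 0.1))
        merged = base.merge(
            more, on=["phase", "source_type", "target_type", "source_gene", "target_gene"]
        )
        assert (merged["score_y"] >= merged["score_x"] - 1e-12).all()

    def test_gate_monotonicity(self, default_sim, default_norm):
        pairs = filter_collagen_pairs(default_interaction_table(), DEFAULT_COLLAGEN_CATALOG)
        sizes = []
        for gate in (0.0, 0.05, 0.1, 0.2, 0.5):
            sizes.append(
                len(score_cci(default_norm, default_sim["meta"], pairs, CCIPairGate(gate, gate)))
            )
        assert sizes == sorted(sizes, reverse=True)


class TestOracleEquivalence:
    def test_empty_pair_table(self):
        norm, meta, _ = _two_type_instance()
        empty = pd.DataFrame({"source_gene": [], "target_gene": []})
        assert oracle_score_cci(norm, meta, empty).empty
        assert score_cci(norm, meta, empty).empty

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fast_implementation_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        norm, meta, pairs = random_cci_instance(rng)
        gate = CCIPairGate(float(rng.choice([0.0, 0.05, 0.2])), 0.1)
        include_self = bool(rng.integers(2))
        fast = score_cci(norm, meta, pairs, gate, include_self)
        slow = oracle_score_cci(norm, meta, pairs, gate, include_self)
        pd.testing.assert_frame_equal(fast, slow, atol=1e-9, rtol=0)


class TestAggregates:
    def test_empty_table_all_totals_zero(self):
        totals = total_cci(pd.DataFrame(columns=["phase", "score"]))
        assert (totals == 0).all()
        assert list(totals.index) == list(PHASES)

    def test_single_phase_rows_leave_others_zero(self):
        scores = pd.DataFrame({"phase": ["pregnancy"] * 3, "score": [1.0, 2.0, 0.5]})
        totals = total_cci(scores)
        assert totals["pregnancy"] == pytest.approx(3.5)
        assert totals[["virgin", "lactation", "involution"]].sum() == 0

    def test_planted_phase_ordering(self, default_sim, default_norm):
        pairs = filter_collagen_pairs(default_interaction_table(), DEFAULT_COLLAGEN_CATALOG)
        totals = total_cci(score_cci(default_norm, default_sim["meta"], pairs))
        assert totals["pregnancy"] > totals["involution"]
        assert totals["involution"] > max(totals["virgin"], totals["lactation"])

    def test_chord_table_single_row(self):
        scores = pd.DataFrame(
            [{"phase": "virgin", "source_type": "T cell", "target_type": "B cell",
              "source_gene": "Col1a1", "target_gene": "Itgb1", "score": 2.5}]
        )
        chord = circos_table(scores)
        assert len(chord) == 1
        assert chord.iloc[0]["score"] == 2.5
        assert chord.iloc[0]["source_group"] == "immune"

    def test_additivity_chord_vs_totals_vs_rows(self, default_sim, default_norm):
        pairs = filter_collagen_pairs(default_interaction_table(), DEFAULT_COLLAGEN_CATALOG)
        scores = score_cci(default_norm, default_sim["meta"], pairs)
        chord = circos_table(scores)
        totals = total_cci(scores)
        for phase in PHASES:
            raw = scores.loc[scores["phase"] == phase, "score"].sum()
            via_chord = chord.loc[chord["phase"] == phase, "score"].sum()
            assert abs(raw - totals[phase]) < 1e-9
            assert abs(via_chord - totals[phase]) < 1e-9

    def test_unmapped_type_rejected(self):
        scores = pd.DataFrame(
            [{"phase": "virgin", "source_type": "mystery", "target_type": "B cell",
              "source_gene": "g", "target_gene": "h", "score": 1.0}]
        )
        with pytest.raises(ValidationError, match="mystery"):
            circos_table(scores)

    def test_immune_source_chords_pregnancy_only(self, default_sim, default_norm):
        pairs = filter_collagen_pairs(default_interaction_table(), DEFAULT_COLLAGEN_CATALOG)
        chord = circos_table(score_cci(default_norm, default_sim["meta"], pairs))
        immune_src = chord[chord["source_group"] == "immune"]
        assert "pregnancy" in set(immune_src["phase"])
        assert "virgin" not in set(immune_src["phase"])
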
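"""Normalization, PCA, clustering and annotation contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammocci.datatypes import DEFAULT_MARKERS, ValidationError
from mammocci.preprocess import (
    ParameterError,
    annotate,
    annotate_clusters,
    cluster_cells,
    log_normalize,
    pca,
)

from conftest import make_matrix


class TestLogNormalize:
    def test_hand_computed_values(self):
        # one cell with counts (1, 3), scale 4: linear values 1 and 3
        norm = log_normalize(make_matrix([[1], [3]]), scale_factor=4)
        vals = norm.values.toarray().ravel()
        assert vals == pytest.approx([np.log(2), np.log(4)])

    def test_equal_counts_give_equal_values(self):
        norm = log_normalize(make_matrix([[5], [5], [5]]))
        vals = norm.values.toarray().ravel()
        assert np.allclose(vals, vals[0])

    def test_zero_count_maps_to_zero(self):
        norm = log_normalize(make_matrix([[0], [2]]))
        assert norm.values.toarray()[0, 0] == 0.0

    def test_per_cell_linear_totals_equal_scale_factor(self, default_norm):
        linear = norm_linear_totals(default_norm)
        assert np.allclose(linear, default_norm.scale_factor, rtol=1e-12)

    def test_zero_total_cell_excluded_with_warning(self):
        m = make_matrix([[1, 0], [2, 0]])
        with pytest.warns(UserWarning, match="zero-total"):
            norm = log_normalize(m)
        assert norm.cell_ids == ["c0"]
        assert norm.dropped_cells == ["c1"]

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError, match="zero total"):
            log_normalize(make_matrix([[0], [0]]))

    @given(multiplier=st.integers(min_value=1, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance_per_cell(self, multiplier):
        base = np.array([[3, 1], [0, 4], [2, 2]])
        scaled = base.copy()
        scaled[:, 0] *= multiplier
        v1 = log_normalize(make_matrix(base)).values.toarray()
        v2 = log_normalize(make_matrix(scaled)).values.toarray()
        assert np.allclose(v1[:, 0], v2[:, 0])


def norm_linear_totals(norm):
    linear = norm.values.copy()
    linear.data = np.expm1(linear.data)
    return np.asarray(linear.sum(axis=0)).ravel()


class TestPCA:
    def test_rank_one_matrix_single_component_explains_all(self):
        from conftest import make_norm_direct

        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([2.0, 1.0, 0.5])
        values = np.outer(v, u)  # genes x cells, rank 1
        norm = make_norm_direct(values, (values > 0).astype(int),
                                ["G0", "G1", "G2"], ["c0", "c1", "c2", "c3"])
        emb = pca(norm, k=1)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-6)

    def test_full_rank_reconstruction_error_zero(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(5, 8))
        counts[0] += 1
        norm = log_normalize(make_matrix(counts))
        x = norm.values.toarray().T
        emb = pca(norm, k=5)
        recon = emb.coords @ emb.loadings + x.mean(axis=0)
        assert np.abs(recon - x).max() < 1e-6

    def test_leading_eigenvalue_matches_direct_eigendecomposition(self):
        # brute-force oracle: eigendecomposition of the 3x3 covariance
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(3, 50)) + 1
        norm = log_normalize(make_matrix(counts))
        x = norm.values.toarray().T
        cov = np.cov(x, rowvar=False, ddof=1)
        top = np.linalg.eigvalsh(cov).max()
        emb = pca(norm, k=3)
        assert emb.explained_variance[0] == pytest.approx(top, rel=1e-9)

    def test_loadings_orthonormal(self, default_norm):
        emb = pca(default_norm, k=10)
        gram = emb.loadings @ emb.loadings.T
        assert np.abs(gram - np.eye(10)).max() < 1e-6

    def test_explained_variance_non_increasing(self, default_norm):
        emb = pca(default_norm, k=10)
        assert (np.diff(emb.explained_variance) <= 1e-12).all()

    def test_k_too_large_rejected(self):
        norm = log_normalize(make_matrix([[1, 2], [3, 4]]))
        with pytest.raises(ParameterError, match="k must be"):
            pca(norm, k=3)

    def test_uncentered_variant_orthonormal(self):
        rng = np.random.default_rng(2)
        norm = log_normalize(make_matrix(rng.poisson(3, size=(6, 12)) + 1))
        emb = pca(norm, k=3, center=False)
        gram = emb.loadings @ emb.loadings.T
        assert np.abs(gram - np.eye(3)).max() < 1e-6


class TestClusterCells:
    @staticmethod
    def _blob_embedding(seed=0):
        from mammocci.preprocess import Embedding

        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(60, 5))
        b = rng.normal(20, 1, size=(60, 5))  # >= 10 sigma separation
        coords = np.vstack([a, b])
        return Embedding(coords, np.eye(5), np.ones(5), np.ones(5) / 5), np.array(
            [0] * 60 + [1] * 60
        )

    def test_two_separated_blobs_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        emb, truth = self._blob_embedding()
        labels = cluster_cells(emb, n_neighbors=10, resolution=0.1, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_blob_low_resolution_one_cluster(self):
        from mammocci.preprocess import Embedding

        rng = np.random.default_rng(3)
        emb = Embedding(rng.normal(size=(80, 4)), np.eye(4), np.ones(4), np.ones(4) / 4)
        labels = cluster_cells(emb, n_neighbors=15, resolution=0.01, seed=0)
        assert len(np.unique(labels)) == 1

    def test_fixed_seed_is_deterministic(self):
        emb, _ = self._blob_embedding(4)
        l1 = cluster_cells(emb, seed=11)
        l2 = cluster_cells(emb, seed=11)
        assert (l1 == l2).all()

    def test_too_few_cells_rejected(self):
        from mammocci.preprocess import Embedding

        emb = Embedding(np.zeros((5, 2)), np.eye(2), np.ones(2), np.ones(2) / 2)
        with pytest.raises(ParameterError, match="n_neighbors"):
            cluster_cells(emb, n_neighbors=10)


class TestAnnotateClusters:
    def test_pure_marker_cluster_labelled(self):
        genes = ["Cd3e", "Cd3d", "Krt8"]
        counts = np.array([[4, 5], [3, 4], [0, 0]])
        norm = log_normalize(make_matrix(counts, genes=genes))
        labels, report = annotate_clusters(
            norm, np.zeros(2, dtype=int), {"T cell": ("Cd3e", "Cd3d"), "luminal": ("Krt8",)}
        )
        assert (labels == "T cell").all()
        assert not report.iloc[0]["low_confidence"]

    def test_tie_breaks_lexicographically_and_flags(self):
        genes = ["A1", "B1"]
        counts = np.array([[3], [3]])
        norm = log_normalize(make_matrix(counts, genes=genes))
        labels, report = annotate_clusters(
            norm, np.zeros(1, dtype=int), {"beta": ("B1",), "alpha": ("A1",)}
        )
        assert labels.iloc[0] == "alpha"
        assert report.iloc[0]["low_confidence"]

    def test_missing_markers_listed(self, default_norm):
        with pytest.raises(ValidationError, match="Nope1"):
            annotate_clusters(
                default_norm, np.zeros(default_norm.n_cells, dtype=int), {"x": ("Nope1",)}
            )

    def test_planted_types_recovered(self, default_sim):
        """Full preprocess chain recovers >=95% of planted cell types."""
        matrix, truth = default_sim["matrix"], default_sim["truth"]
        _, cells, _ = annotate(matrix, dict(DEFAULT_MARKERS), seed=0)
        acc = np.mean(
            [truth.cell_type_of_cell[c] == t for c, t in zip(cells["cell_id"], cells["cell_type"])]
        )
        assert acc >= 0.95
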
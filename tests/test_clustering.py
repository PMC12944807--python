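"""Similarity graph, normalized Laplacian, embedding and discretization."""

import itertools

import numpy as np
import pytest
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from vibroclust.clustering import (
    DegenerateSpectrumError,
    Embedding,
    SimilarityMatrix,
    cluster_spectra,
    discretize,
    laplacian_sym,
    pearson_similarity,
    silhouette_select_k,
    spectral_embed,
)
from vibroclust.labeling import Labeling
from vibroclust.metrics import adjusted_mutual_information
from vibroclust.spectra import BroadeningParams, FrequencyGrid, GridSpectrum, broaden
from vibroclust.synthetic import default_templates, generate_dataset, noiseless

GRID = FrequencyGrid(0.0, 30.0, 10.0)  # 4 points: enough for correlation tests


def grid_spectrum(values, cid, grid=GRID):
    return GridSpectrum(cid, grid, np.asarray(values, dtype=float))


def random_similarity(rng, n):
    S = rng.random((n, n))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(tuple(range(n)), S)


def block_similarity(sizes, rng=None):
    """Exact block-diagonal similarity: 1 within blocks, 0 between."""
    n = sum(sizes)
    S = np.zeros((n, n))
    start = 0
    for size in sizes:
        S[start : start + size, start : start + size] = 1.0
        start += size
    return SimilarityMatrix(tuple(range(n)), S)


class TestPearsonSimilarity:
    def test_identical_spectra_correlate_perfectly(self):
        a = grid_spectrum([1, 2, 3, 4], "a")
        b = grid_spectrum([1, 2, 3, 4], "b")
        S = pearson_similarity([a, b])
        assert S.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        S = pearson_similarity([grid_spectrum(x, "a"), grid_spectrum(2 * x + 3, "b")])
        assert S.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_known_correlation_value(self):
        S = pearson_similarity(
            [grid_spectrum([1, 2, 3, 4], "a"), grid_spectrum([1, 3, 2, 4], "b")]
        )
        assert S.values[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_constant_spectrum_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError, match="flat"):
            pearson_similarity(
                [grid_spectrum([1, 2, 3, 4], "a"), grid_spectrum([2, 2, 2, 2], "flat")]
            )

    def test_mismatched_grids_rejected(self):
        other = FrequencyGrid(0.0, 3.0, 1.0)
        with pytest.raises(ValueError, match="common grid"):
            pearson_similarity(
                [grid_spectrum([1, 2, 3, 4], "a"), grid_spectrum([1, 2, 3, 4], "b", other)]
            )

    @pytest.mark.parametrize("policy,expected", [("clip", 0.0), ("shift", 0.0)])
    def test_negative_correlations_become_nonnegative(self, policy, expected):
        S = pearson_similarity(
            [grid_spectrum([1, 2, 3, 4], "a"), grid_spectrum([4, 3, 2, 1], "b")],
            clip_policy=policy,
        )
        assert S.values[0, 1] == pytest.approx(expected, abs=1e-12)


class TestLaplacian:
    def test_identity_similarity_gives_zero_laplacian(self):
        S = SimilarityMatrix(tuple(range(4)), np.eye(4))
        L, d = laplacian_sym(S)
        assert np.allclose(L, 0.0)
        assert np.allclose(d, 1.0)

    @pytest.mark.parametrize("s", [0.1, 0.5, 0.9, 1.0])
    def test_two_node_eigenvalues_closed_form(self, s):
        S = SimilarityMatrix((0, 1), np.array([[1.0, s], [s, 1.0]]))
        L, _ = laplacian_sym(S)
        eig = np.sort(scipy.linalg.eigvalsh(L))
        assert eig == pytest.approx([0.0, 2.0 * s / (1.0 + s)], abs=1e-12)

    def test_sqrt_degree_is_null_vector(self, rng):
        S = random_similarity(rng, 7)
        L, d = laplacian_sym(S)
        v = np.sqrt(d)
        assert np.allclose(L @ v, 0.0, atol=1e-10)

    def test_eigenvalues_within_zero_two(self, rng):
        for _ in range(10):
            L, _ = laplacian_sym(random_similarity(rng, 8))
            eig = scipy.linalg.eigvalsh(L)
            assert eig.min() >= -1e-8
            assert eig.max() <= 2.0 + 1e-8

    def test_zero_eigenvalue_multiplicity_counts_components(self, rng):
        for sizes in [(3, 4), (2, 2, 5), (1, 3, 3, 4)]:
            S = block_similarity(sizes)
            # perturb within-block weights, keep blocks disconnected
            noise = 0.1 * rng.random(S.values.shape)
            noisy = np.where(S.values > 0, np.clip(S.values - noise, 0.2, 1.0), 0.0)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 1.0)
            S = SimilarityMatrix(S.ids, noisy)
            L, _ = laplacian_sym(S)
            eig = scipy.linalg.eigvalsh(L)
            adjacency = (S.values > 0).astype(int)
            n_components, _ = connected_components(adjacency, directed=False)
            assert n_components == len(sizes)
            assert int((eig < 1e-8).sum()) == len(sizes)


class TestSpectralEmbed:
    def test_disconnected_blocks_have_zero_eigenvalues(self):
        S = block_similarity((3, 3, 4))
        L, _ = laplacian_sym(S)
        emb = spectral_embed(L, 3, ids=S.ids)
        assert np.allclose(emb.eigenvalues, 0.0, atol=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        # path-like 3-node graph against a full eigensolver
        S = SimilarityMatrix((0, 1, 2), np.array([
            [1.0, 0.6, 0.1],
            [0.6, 1.0, 0.6],
            [0.1, 0.6, 1.0],
        ]))
        L, _ = laplacian_sym(S)
        emb = spectral_embed(L, 2, ids=S.ids)
        full = np.sort(scipy.linalg.eigvalsh(L))
        assert np.allclose(emb.eigenvalues, full[:2], atol=1e-10)

    def test_k_n_minus_one_columns_orthonormal(self, rng):
        S = random_similarity(rng, 6)
        L, _ = laplacian_sym(S)
        emb = spectral_embed(L, 5, ids=S.ids)
        assert np.allclose(emb.U.T @ emb.U, np.eye(5), atol=1e-8)

    @pytest.mark.parametrize("k", [0, 1, 6, 10])
    def test_k_out_of_range_rejected(self, rng, k):
        S = random_similarity(rng, 6)
        L, _ = laplacian_sym(S)
        with pytest.raises(ValueError):
            spectral_embed(L, k, ids=S.ids)


def best_two_partition(dist):
    """Exhaustive 2-partition minimizing total within-cluster distance."""
    n = dist.shape[0]
    best_cost, best = np.inf, None
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if mask.all() or not mask.any():
            continue
        cost = dist[np.ix_(mask, mask)].sum() + dist[np.ix_(~mask, ~mask)].sum()
        if cost < best_cost:
            best_cost, best = cost, mask.copy()
    return best


class TestDiscretize:
    def test_indicator_matrix_is_fixed_point(self):
        rows = np.array([0, 0, 1, 2, 1, 2, 0])
        U = np.zeros((7, 3))
        U[np.arange(7), rows] = 1.0
        # orthonormalize columns (divide by sqrt of cluster size)
        U = U / np.sqrt(U.sum(axis=0, keepdims=True))
        emb = Embedding(tuple(range(7)), U, np.array([0.0, 0.0, 0.0]))
        labels = discretize(emb, seed=0)
        assert (
            adjusted_mutual_information(
                labels, Labeling(tuple(range(7)), tuple(rows))
            ).value
            == pytest.approx(1.0, abs=1e-12)
        )

    def test_duplicate_rows_co_clustered(self, rng):
        S = block_similarity((4, 4))
        L, _ = laplacian_sym(S)
        emb = spectral_embed(L, 2, ids=S.ids)
        labels = discretize(emb, seed=1)
        codes = labels.codes()
        assert len(set(codes[:4])) == 1 and len(set(codes[4:])) == 1

    def test_two_blob_partition_matches_exhaustive_best_cut(self, rng):
        """Well-separated 2-D blobs: pipeline = brute-force optimal 2-cut."""
        pts = np.vstack([
            rng.normal([0.0, 0.0], 0.2, size=(5, 2)),
            rng.normal([4.0, 4.0], 0.2, size=(6, 2)),
        ])
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        S_values = np.exp(-(dist**2) / 2.0)
        np.fill_diagonal(S_values, 1.0)
        S = SimilarityMatrix(tuple(range(11)), S_values)
        L, _ = laplacian_sym(S)
        labels = discretize(spectral_embed(L, 2, ids=S.ids), seed=0).codes()
        oracle_mask = best_two_partition(dist)
        assert (
            adjusted_mutual_information(
                Labeling(S.ids, tuple(labels)), Labeling(S.ids, tuple(oracle_mask))
            ).value
            == pytest.approx(1.0, abs=1e-12)
        )

    def test_agrees_with_reference_spectral_clustering(self, rng):
        """>= 45/50 planted instances match scikit-learn's discretize labels."""
        from sklearn.cluster import SpectralClustering
        from sklearn.metrics import adjusted_mutual_info_score

        agree = 0
        for trial in range(50):
            k = int(rng.integers(2, 5))
            sizes = rng.integers(3, 7, size=k)
            n = int(sizes.sum())
            truth = np.repeat(np.arange(k), sizes)[rng.permutation(n)]
            within = truth[:, None] == truth[None, :]
            S_values = np.where(within, 0.8 + 0.15 * rng.random((n, n)),
                                0.1 * rng.random((n, n)))
            S_values = (S_values + S_values.T) / 2.0
            np.fill_diagonal(S_values, 1.0)
            S = SimilarityMatrix(tuple(range(n)), S_values)
            L, _ = laplacian_sym(S)
            ours = discretize(spectral_embed(L, k, ids=S.ids), seed=trial).codes()
            ref = SpectralClustering(
                n_clusters=k, affinity="precomputed",
                assign_labels="discretize", random_state=trial,
            ).fit(S_values)
            if adjusted_mutual_info_score(ours, ref.labels_) >= 0.95:
                agree += 1
        assert agree >= 45


def synthetic_grid_spectra(n_classes=3, seed=0, jitter_sd=2.0, n_per_class=5):
    templates = default_templates()[:n_classes]
    ds = generate_dataset(templates, n_per_class=n_per_class, seed=seed, jitter_sd=jitter_sd)
    grid = FrequencyGrid(400.0, 1800.0, 2.0)
    return [broaden(s, grid) for s in ds.spectra], ds.truth


class TestPipeline:
    def test_duplicated_groups_separate_perfectly(self):
        grid = FrequencyGrid(0.0, 90.0, 10.0)
        rng = np.random.default_rng(3)
        a = rng.random(10)
        b = rng.random(10)
        spectra = [
            GridSpectrum(f"a{i}", grid, a + 0.001 * i) for i in range(3)
        ] + [
            GridSpectrum(f"b{i}", grid, b + 0.001 * i) for i in range(3)
        ]
        result = cluster_spectra(spectra, k=2, seed=0)
        codes = result.labeling.codes()
        assert len(set(codes[:3])) == 1 and len(set(codes[3:])) == 1

    def test_synthetic_five_class_recovery(self):
        grids, truth = synthetic_grid_spectra(n_classes=5, seed=11, jitter_sd=5.0)
        result = cluster_spectra(grids, k=5, seed=0)
        assert adjusted_mutual_information(result.labeling, truth).value >= 0.9

    def test_same_seed_reproduces_labels(self):
        grids, _ = synthetic_grid_spectra(seed=4)
        first = cluster_spectra(grids, k=3, seed=7)
        second = cluster_spectra(grids, k=3, seed=7)
        assert first.labeling == second.labeling

    def test_invariant_to_input_order(self):
        grids, _ = synthetic_grid_spectra(seed=5)
        base = cluster_spectra(grids, k=3, seed=0)
        shuffled = [grids[i] for i in np.random.default_rng(9).permutation(len(grids))]
        permuted = cluster_spectra(shuffled, k=3, seed=0)
        a = Labeling.from_dict(base.labeling.to_dict())
        b = Labeling.from_dict(permuted.labeling.to_dict())
        assert adjusted_mutual_information(a, b).value == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_common_affine_intensity_change(self):
        grids, _ = synthetic_grid_spectra(seed=6)
        base = cluster_spectra(grids, k=3, seed=0)
        transformed = [
            GridSpectrum(g.compound_id, g.grid, 3.5 * g.intensities + 10.0, g.kind)
            for g in grids
        ]
        other = cluster_spectra(transformed, k=3, seed=0)
        assert adjusted_mutual_information(base.labeling, other.labeling).value == (
            pytest.approx(1.0, abs=1e-12)
        )


class TestSelectK:
    def test_three_planted_classes_select_k_three(self):
        grids, truth = synthetic_grid_spectra(n_classes=3, seed=1, jitter_sd=2.0)
        result = silhouette_select_k(grids, k_min=2, k_max=8, seed=0)
        assert result.k == 3
        assert adjusted_mutual_information(result.labeling, truth).value >= 0.9

    def test_single_candidate_range(self):
        grids, _ = synthetic_grid_spectra(seed=2)
        result = silhouette_select_k(grids, k_min=2, k_max=2, seed=0)
        assert result.k == 2

    def test_invalid_range_rejected(self):
        grids, _ = synthetic_grid_spectra(seed=2)
        with pytest.raises(ValueError):
            silhouette_select_k(grids, k_min=2, k_max=len(grids))
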
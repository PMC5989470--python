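"""PCA, SNN graph construction, modularity clustering, tSNE plumbing."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse
from sklearn.metrics import adjusted_rand_score

import scfidelity as sf
from scfidelity.preprocess import NormalizedMatrix


def as_nm(values: np.ndarray) -> NormalizedMatrix:
    df = pd.DataFrame(
        values,
        index=[f"c{i}" for i in range(values.shape[0])],
        columns=[f"g{j}" for j in range(values.shape[1])],
    )
    return NormalizedMatrix(values=df, scale_factor=1e4)


def pca_of(values, n_pcs, clip=10.0):
    nm = as_nm(values)
    return sf.run_pca(nm, list(nm.values.columns), n_pcs=n_pcs, clip=clip)


class TestPCA:
    def test_planar_data_has_no_variance_beyond_rank(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        coords = rng.normal(size=(30, 2))
        p = pca_of(coords @ basis, n_pcs=5)
        assert p.explained_variance[2:].max() <= 1e-10

    def test_duplicating_cells_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 6))
        a = pca_of(X, n_pcs=3)
        b = pca_of(np.vstack([X, X]), n_pcs=3)
        np.testing.assert_allclose(
            a.gene_loadings.to_numpy(), b.gene_loadings.to_numpy(), atol=1e-8
        )

    def test_matches_covariance_eigendecomposition(self):
        """5x4 toy matrix: embeddings equal a brute-force eigendecomposition
        of the covariance of the z-scored data, to 1e-8."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 4))
        p = pca_of(X, n_pcs=3, clip=1e9)
        z = (X - X.mean(0)) / X.std(0, ddof=1)
        cov = z.T @ z / (z.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for i in range(3):
            v = evecs[:, i]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(p.gene_loadings.to_numpy()[:, i], v, atol=1e-8)
            np.testing.assert_allclose(p.cell_embeddings.to_numpy()[:, i], z @ v, atol=1e-8)
        np.testing.assert_allclose(p.explained_variance, evals[:3], atol=1e-8)

    def test_n_pcs_beyond_dimensions_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="exceeds"):
            pca_of(rng.normal(size=(5, 4)), n_pcs=5)

    def test_sign_convention_makes_runs_identical(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 8))
        a = pca_of(X, n_pcs=4)
        b = pca_of(X, n_pcs=4)
        assert np.array_equal(a.cell_embeddings.to_numpy(), b.cell_embeddings.to_numpy())
        # largest-magnitude loading of every component is positive
        load = a.gene_loadings.to_numpy()
        assert all(load[np.argmax(np.abs(load[:, i])), i] > 0 for i in range(4))


def snn_bruteforce(emb: np.ndarray, k: int, prune: float) -> np.ndarray:
    """Set-arithmetic oracle: k-nearest sets (self included) and explicit
    Jaccard overlaps."""
    n = emb.shape[0]
    d = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
    sets = [set(np.argsort(d[i], kind="stable")[:k]) for i in range(n)]
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = len(sets[i] & sets[j]) / len(sets[i] | sets[j])
            W[i, j] = w if w > prune else 0.0
    return W


def embed(points: np.ndarray) -> sf.PCAResult:
    n, k = points.shape
    return sf.PCAResult(
        cell_embeddings=pd.DataFrame(
            points, index=[f"c{i}" for i in range(n)],
            columns=[f"PC{j + 1}" for j in range(k)],
        ),
        gene_loadings=pd.DataFrame(),
        explained_variance=np.array([]),
    )


class TestSNNGraph:
    def test_identical_neighborhoods_weight_one(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2)) * 10
        pts[1] = pts[0]  # coincident pair among well-spread points
        g = sf.build_snn_graph(embed(pts), k=3, prune=0.0)
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_distant_clouds_have_no_cross_edges(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(15, 2))
        b = rng.normal(size=(15, 2)) + 1000.0
        g = sf.build_snn_graph(embed(np.vstack([a, b])), k=5, prune=0.0)
        cross = g.weights[:15, 15:]
        assert cross.nnz == 0

    @pytest.mark.parametrize("n,k,prune,seed", [
        (10, 3, 0.0, 0), (25, 5, 1 / 15, 1), (50, 8, 1 / 15, 2), (40, 12, 0.2, 3),
    ])
    def test_weights_match_set_arithmetic_oracle(self, n, k, prune, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        g = sf.build_snn_graph(embed(pts), k=k, prune=prune)
        np.testing.assert_allclose(
            g.weights.toarray(), snn_bruteforce(pts, k, prune), atol=1e-12
        )

    def test_graph_is_symmetric_with_unit_bound(self):
        rng = np.random.default_rng(7)
        g = sf.build_snn_graph(embed(rng.normal(size=(30, 4))), k=6)
        W = g.weights.toarray()
        assert np.allclose(W, W.T)
        assert W.max() <= 1.0
        assert np.diag(W).sum() == 0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            sf.build_snn_graph(embed(np.zeros((5, 2))), k=0)


def graph_from_dense(W: np.ndarray) -> sf.SNNGraph:
    return sf.SNNGraph(
        cell_ids=[f"c{i}" for i in range(W.shape[0])],
        weights=scipy.sparse.csr_matrix(W),
        k=0, prune=0.0,
    )


class TestClusterGraph:
    def two_cliques(self, size=6):
        W = np.zeros((2 * size, 2 * size))
        W[:size, :size] = 1.0
        W[size:, size:] = 1.0
        np.fill_diagonal(W, 0.0)
        return W

    def test_disconnected_cliques_split_exactly(self):
        labels = sf.cluster_graph(graph_from_dense(self.two_cliques()), resolution=1.0, seed=0)
        arr = labels.labels.to_numpy()
        assert labels.n_clusters == 2
        assert len(set(arr[:6])) == 1 and len(set(arr[6:])) == 1
        assert arr[0] != arr[6]

    def test_vanishing_resolution_merges_connected_graph(self):
        W = self.two_cliques()
        W[0, 6] = W[6, 0] = 0.5  # bridge
        labels = sf.cluster_graph(graph_from_dense(W), resolution=1e-4, seed=0)
        assert labels.n_clusters == 1

    def test_labels_contiguous_from_zero(self, bench_pipeline):
        labels = bench_pipeline["labels"]
        assert sorted(labels.labels.unique()) == list(range(labels.n_clusters))

    def test_recovers_planted_programs(self, bench_pipeline):
        ari = adjusted_rand_score(bench_pipeline["true_labels"], bench_pipeline["labels"].labels)
        assert ari >= 0.9

    def test_permutation_invariant_up_to_relabeling(self, bench_pipeline):
        pca = bench_pipeline["pca"]
        rng = np.random.default_rng(8)
        perm = rng.permutation(pca.cell_embeddings.shape[0])
        permuted = sf.PCAResult(
            cell_embeddings=pca.cell_embeddings.iloc[perm],
            gene_loadings=pca.gene_loadings,
            explained_variance=pca.explained_variance,
        )
        snn_p = sf.build_snn_graph(permuted, k=20, prune=1 / 15)
        labels_p = sf.cluster_graph(snn_p, resolution=1.0, seed=1)
        orig = bench_pipeline["labels"].labels
        ari = adjusted_rand_score(
            orig.loc[labels_p.labels.index], labels_p.labels
        )
        assert ari == pytest.approx(1.0)

    def test_leiden_also_recovers_planted_programs(self, bench_pipeline):
        labels = sf.cluster_graph(bench_pipeline["snn"], resolution=1.0, seed=1, method="leiden")
        ari = adjusted_rand_score(bench_pipeline["true_labels"], labels.labels)
        assert ari >= 0.9


class TestTSNE:
    def test_output_shape_and_determinism(self):
        rng = np.random.default_rng(9)
        p = embed(rng.normal(size=(60, 5)))
        a = sf.run_tsne(p, iterations=250, seed=3, perplexity=10)
        b = sf.run_tsne(p, iterations=250, seed=3, perplexity=10)
        assert a.shape == (60, 2)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_perplexity_bound_enforced(self):
        p = embed(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="perplexity"):
            sf.run_tsne(p, perplexity=10)
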
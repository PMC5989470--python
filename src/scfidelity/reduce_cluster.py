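"""PCA over variable genes, SNN graph construction, and modularity clustering.

The clustering route mirrors the classic graph-based scRNA-seq workflow:
per-gene z-scoring (clipped), exact PCA, a shared-nearest-neighbor (SNN)
graph whose edge weights are Jaccard overlaps of k-nearest-neighbor sets in
PC space (self included in each neighbor list), and Louvain modularity
optimization with a resolution parameter scaling the null-model term.
Leiden is available as an alternative.  A tSNE embedding is provided for
visualization only.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .preprocess import NormalizedMatrix, VariableGeneSet

__all__ = [
    "PCATransformer",
    "PCAResult",
    "SNNGraph",
    "ClusterAssignment",
    "run_pca",
    "build_snn_graph",
    "cluster_graph",
    "run_tsne",
]


@dataclass
class PCAResult:
    """Cell scores, gene loadings and explained variance of an exact PCA."""

    cell_embeddings: pd.DataFrame  # cells x PCs
    gene_loadings: pd.DataFrame  # genes x PCs
    explained_variance: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.cell_embeddings.shape[1]


@dataclass
class SNNGraph:
    """Symmetric SNN graph; ``weights`` is a sparse cells x cells matrix of
    Jaccard overlaps in (0, 1], with no self-loops."""

    cell_ids: list[str]
    weights: scipy.sparse.csr_matrix
    k: int
    prune: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class ClusterAssignment:
    """Per-cell integer cluster labels, contiguous from 0."""

    labels: pd.Series
    resolution: float
    seed: int
    method: str = "louvain"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cells_in(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


class PCATransformer(TransformerMixin, BaseEstimator):
    """Z-score (clipped) then exact PCA with a fixed sign convention.

    Each gene is centered and scaled to unit variance (n-1 denominator)
    across cells; zero-variance genes map to 0.  Z-scores are clipped to
    ``+-clip`` before the decomposition.  Component signs are fixed by
    making the largest-magnitude gene loading of each component positive,
    so results are reproducible bit-for-bit.
    """

    def __init__(self, n_components: int = 12, clip: float = 10.0):
        self.n_components = n_components
        self.clip = clip

    def _scale(self, X: pd.DataFrame) -> np.ndarray:
        values = X.to_numpy(dtype=float)
        z = (values - self.mean_) / np.where(self.std_ > 0, self.std_, 1.0)
        z[:, self.std_ == 0] = 0.0
        return np.clip(z, -self.clip, self.clip)

    def fit(self, X: pd.DataFrame, y=None) -> "PCATransformer":
        n_cells, n_genes = X.shape
        if self.n_components > min(n_cells, n_genes):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(cells, genes)="
                f"{min(n_cells, n_genes)}"
            )
        values = X.to_numpy(dtype=float)
        self.mean_ = values.mean(axis=0)
        self.std_ = values.std(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
        z = self._scale(X)
        pca = PCA(n_components=self.n_components, svd_solver="full")
        emb = pca.fit_transform(z)
        comps = pca.components_
        for i in range(comps.shape[0]):
            j = int(np.argmax(np.abs(comps[i])))
            if comps[i, j] < 0:
                comps[i] *= -1
                emb[:, i] *= -1
        self.components_ = comps
        self.explained_variance_ = pca.explained_variance_
        self._fit_embeddings = emb
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        z = self._scale(X)
        return z @ self.components_.T

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        self.fit(X)
        return self._fit_embeddings


def run_pca(
    nm: NormalizedMatrix,
    genes: VariableGeneSet | list[str],
    n_pcs: int = 12,
    clip: float = 10.0,
) -> PCAResult:
    """Exact PCA of the normalized matrix restricted to the given genes."""
    gene_list = genes.genes if isinstance(genes, VariableGeneSet) else list(genes)
    if not gene_list:
        raise ValueError("empty variable-gene set")
    X = nm.values.loc[:, gene_list]
    t = PCATransformer(n_components=n_pcs, clip=clip)
    emb = t.fit_transform(X)
    pc_names = [f"PC{i + 1}" for i in range(n_pcs)]
    return PCAResult(
        cell_embeddings=pd.DataFrame(emb, index=nm.values.index, columns=pc_names),
        gene_loadings=pd.DataFrame(t.components_.T, index=gene_list, columns=pc_names),
        explained_variance=t.explained_variance_,
    )


def build_snn_graph(p: PCAResult, k: int = 20, prune: float = 1.0 / 15.0) -> SNNGraph:
    """SNN graph from k-nearest neighbors (Euclidean, self included).

    The edge weight between cells i and j is the Jaccard overlap
    |N(i) & N(j)| / |N(i) | N(j)| of their k-neighbor sets; edges with
    weight <= ``prune`` are removed.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    emb = p.cell_embeddings.to_numpy()
    n = emb.shape[0]
    if k >= n + 1:
        raise ValueError(f"k={k} must be < number of cells + 1 ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    idx = nn.kneighbors(emb, return_distance=False)
    # guarantee self-membership: under exact ties self may be displaced
    rows = np.arange(n)
    has_self = (idx == rows[:, None]).any(axis=1)
    idx[~has_self, -1] = rows[~has_self]
    membership = scipy.sparse.csr_matrix(
        (np.ones(n * k, dtype=np.int32), (np.repeat(rows, k), idx.ravel())), shape=(n, n)
    )
    inter = (membership @ membership.T).tocoo()
    union = 2 * k - inter.data
    weights = inter.data / union
    keep = (weights > prune) & (inter.row != inter.col)
    w = scipy.sparse.csr_matrix(
        (weights[keep], (inter.row[keep], inter.col[keep])), shape=(n, n)
    )
    return SNNGraph(cell_ids=list(p.cell_embeddings.index), weights=w, k=k, prune=prune)


def cluster_graph(
    g: SNNGraph, resolution: float = 1.35, seed: int = 0, method: str = "louvain"
) -> ClusterAssignment:
    """Modularity community detection on the SNN graph.

    Louvain (multilevel) by default, with the resolution parameter scaling
    the null-model term; Leiden via ``method='leiden'``.  Deterministic
    given ``seed``.  Isolated cells become singleton clusters.  Labels are
    relabeled to be contiguous from 0, ordered by decreasing cluster size.
    """
    if g.n_cells == 0:
        raise ValueError("empty graph")
    coo = scipy.sparse.triu(g.weights, k=1).tocoo()
    graph = igraph.Graph(
        n=g.n_cells, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    edge_weights = coo.data.tolist()
    if method == "louvain":
        igraph.set_random_number_generator(_pyrandom.Random(seed))
        part = graph.community_multilevel(
            weights=edge_weights or None, resolution=resolution
        )
        membership = np.asarray(part.membership)
    elif method == "leiden":
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=edge_weights or None,
            resolution_parameter=resolution,
            seed=seed,
        )
        membership = np.asarray(part.membership)
    else:
        raise ValueError("method must be 'louvain' or 'leiden'")
    labels = _relabel_by_size(membership)
    return ClusterAssignment(
        labels=pd.Series(labels, index=g.cell_ids, name="cluster"),
        resolution=resolution,
        seed=seed,
        method=method,
    )


def _relabel_by_size(membership: np.ndarray) -> np.ndarray:
    ids, sizes = np.unique(membership, return_counts=True)
    first_seen = {c: int(np.argmax(membership == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-sizes[list(ids).index(c)], first_seen[c]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in membership], dtype=int)


def run_tsne(
    p: PCAResult, iterations: int = 1000, seed: int = 0, perplexity: float = 30.0
) -> pd.DataFrame:
    """2-D tSNE of the PC embeddings (visualization only)."""
    n = p.cell_embeddings.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of cells ({n})")
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max(int(iterations), 250),
        random_state=seed,
        init="pca",
    )
    coords = ts.fit_transform(p.cell_embeddings.to_numpy())
    return pd.DataFrame(coords, index=p.cell_embeddings.index, columns=["tSNE1", "tSNE2"])
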
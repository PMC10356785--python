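"""Three seeded clustering backends for consensus phenotyping.

Backend 1 is community detection (Leiden) on a Jaccard-weighted k-nearest-
neighbour graph (PhenoGraph family, k = 30 by default); the number of
communities it finds fixes k for backend 2 (a self-organizing map followed
by Ward metaclustering of the codebook, FlowSOM family) and backend 3
(k-means).  All three are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

__all__ = ["ClusteringConfig", "run_backends", "graph_community", "som_metacluster", "kmeans_cluster"]

BACKENDS = ("graph", "som", "kmeans")


@dataclass
class ClusteringConfig:
    """Backend parameters.  ``n_clusters=None`` lets the graph backend set k."""

    k_graph: int = 30
    som_shape: tuple = (10, 10)
    som_epochs: int = 10
    n_clusters: int | None = None
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_graph < 2:
            raise ValueError("k_graph must be >= 2")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


def _jaccard_knn_graph(X: np.ndarray, k: int) -> igraph.Graph:
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(X)
    _, idx = nn.kneighbors(X)
    idx = idx[:, 1:]  # drop self
    k_eff = idx.shape[1]
    rows = np.repeat(np.arange(n), k_eff)
    A = csr_matrix((np.ones(n * k_eff), (rows, idx.ravel())), shape=(n, n))
    shared = (A @ A.T).tocsr()  # |N_i & N_j| for all i, j with shared neighbours
    sym = A.maximum(A.T).tocoo()  # candidate edges: i in N(j) or j in N(i)
    upper = sym.row < sym.col
    ei, ej = sym.row[upper], sym.col[upper]
    inter = np.asarray(shared[ei, ej]).ravel()
    weights = inter / (2 * k_eff - inter)
    g = igraph.Graph(n=n, edges=np.column_stack([ei, ej]).tolist())
    g.es["weight"] = weights.tolist()
    return g


def graph_community(X: np.ndarray, k_graph: int = 30, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden communities on the Jaccard-weighted kNN graph."""
    if X.shape[0] < k_graph + 1:
        raise ValueError(f"need more than k_graph={k_graph} cells")
    g = _jaccard_knn_graph(np.asarray(X, dtype=float), k_graph)
    if resolution == 1.0:
        # classic modularity, the PhenoGraph-family default
        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, weights="weight", seed=int(seed)
        )
    else:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=int(seed),
        )
    return np.asarray(part.membership, dtype=int)


def _som_fit(X: np.ndarray, shape: tuple, epochs: int, rng: np.random.Generator) -> np.ndarray:
    """Batch self-organizing map; returns the (n_nodes, n_features) codebook."""
    n_nodes = shape[0] * shape[1]
    gx, gy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
    code = X[rng.choice(X.shape[0], size=n_nodes, replace=X.shape[0] < n_nodes)]
    sigma0 = max(shape) / 2.0
    from scipy.spatial.distance import cdist

    for t in range(epochs):
        sigma = max(sigma0 * (1 - t / epochs), 0.5)
        bmu = cdist(X, code, "sqeuclidean").argmin(axis=1)
        h = np.exp(-grid_d2 / (2 * sigma**2))  # (nodes, nodes)
        w = h[bmu]  # (n, nodes): pull of each point on each node
        denom = w.sum(axis=0)
        num = w.T @ X
        nonzero = denom > 1e-12
        code[nonzero] = num[nonzero] / denom[nonzero, None]
    return code


def som_metacluster(
    X: np.ndarray,
    n_clusters: int,
    shape: tuple = (10, 10),
    epochs: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """SOM codebook + Ward hierarchical metaclustering to ``n_clusters``."""
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    code = _som_fit(X, shape, epochs, rng)
    if n_clusters <= 1:
        return np.zeros(X.shape[0], dtype=int)
    from scipy.spatial.distance import cdist

    Z = linkage(code, method="ward")
    meta = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    bmu = cdist(X, code, "sqeuclidean").argmin(axis=1)
    return meta[bmu]


def kmeans_cluster(X: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    if n_clusters <= 1:
        return np.zeros(np.asarray(X).shape[0], dtype=int)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(np.asarray(X, dtype=float))


def run_backends(X: np.ndarray, cfg: ClusteringConfig | None = None) -> dict[str, np.ndarray]:
    """Run the three backends; k for SOM and k-means follows the graph backend.

    Returns ``{"graph": labels, "som": labels, "kmeans": labels}``.
    If ``cfg.n_clusters`` is set it overrides the graph-derived k for the
    SOM and k-means backends (the graph partition itself is unaffected).
    """
    cfg = cfg or ClusteringConfig()
    X = np.asarray(X, dtype=float)
    graph_labels = graph_community(X, cfg.k_graph, cfg.resolution, cfg.seed)
    k = cfg.n_clusters if cfg.n_clusters is not None else int(graph_labels.max()) + 1
    som_labels = som_metacluster(X, k, cfg.som_shape, cfg.som_epochs, seed=cfg.seed + 1)
    km_labels = kmeans_cluster(X, k, seed=cfg.seed + 2)
    return {"graph": graph_labels, "som": som_labels, "kmeans": km_labels}
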
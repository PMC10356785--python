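"""Consensus cell phenotyping from multiplexed-IF marker intensities.

The chain mirrors a consensus cytometry workflow: per-region Z-scoring,
stratified subsampling, three clustering backends, automated cluster
annotation against expected marker signatures, a 2-of-3 majority vote per
cell ("NOS" when all three disagree), and extrapolation of the voted labels
to the full dataset by projecting every cell into a 2-D embedding built
from a per-type template (up to 500 cells per type) and taking the modal
label of its 100 nearest template cells.

Cluster annotation is automated: each cluster is assigned the phenotype
whose signature profile best correlates (Pearson) with the cluster's mean
Z-profile, with a minimum match score below which the cluster is "NOS".
This stands in for expert manual annotation, which is not reproducible in
software.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .clustering import ClusteringConfig, run_backends
from .normalize import NormalizationConfig, normalize_mfi, z_columns
from .sampling import stratified_sample

__all__ = [
    "NOS",
    "annotate_clusters",
    "consensus_vote",
    "extrapolate_labels",
    "subcluster_myeloid",
    "ConsensusPhenotyper",
    "read_signatures",
]

NOS = "NOS"

_CODE_MAP = {"+": 1.0, "-": -1.0, ".": 0.0, "·": 0.0}


def read_signatures(path) -> pd.DataFrame:
    """Read a phenotype x marker signature TSV; +/-/. codes become numbers."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    return sig.map(lambda v: _CODE_MAP.get(v, v)).astype(float)


def annotate_clusters(
    partition: np.ndarray,
    Z: np.ndarray,
    signatures: pd.DataFrame,
    min_match_r: float = 0.3,
) -> dict[int, str]:
    """Map each cluster id to the best-correlated phenotype signature.

    ``signatures`` is phenotype x marker (numeric); columns must align with
    the columns of ``Z``.  A cluster whose centroid correlates below
    ``min_match_r`` with every signature is "NOS".  Ties break by signature
    row order.
    """
    if signatures.shape[0] < 1:
        raise ValueError("need at least one signature")
    if signatures.shape[1] != Z.shape[1]:
        raise ValueError("signature profile dimension must equal the marker panel dimension")
    partition = np.asarray(partition)
    sig = signatures.to_numpy(dtype=float)
    names = list(signatures.index)
    mapping: dict[int, str] = {}
    for cl in np.unique(partition):
        members = partition == cl
        if not members.any():
            raise ValueError(f"empty cluster {cl}")
        centroid = Z[members].mean(axis=0)
        best_name, best_r = NOS, -np.inf
        for name, profile in zip(names, sig):
            if np.std(centroid) == 0 or np.std(profile) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(centroid, profile)[0, 1])
            if r > best_r:  # strict: ties keep the earlier signature
                best_name, best_r = name, r
        mapping[int(cl)] = best_name if best_r >= min_match_r else NOS
    return mapping


def consensus_vote(labels_1, labels_2, labels_3) -> np.ndarray:
    """Majority phenotype if at least two backends agree, else NOS.

    Permutation-invariant in its three arguments.
    """
    a, b, c = (np.asarray(l, dtype=object) for l in (labels_1, labels_2, labels_3))
    if not (len(a) == len(b) == len(c)):
        raise ValueError("label vectors must have equal length")
    out = np.full(len(a), NOS, dtype=object)
    out[b == c] = b[b == c]
    out[a == c] = a[a == c]
    out[a == b] = a[a == b]
    return out


def _fit_embedder(X: np.ndarray, method: str, seed: int | None):
    if method == "umap":
        import umap

        return umap.UMAP(n_components=2, random_state=seed if seed is not None else 0).fit(X)
    if method == "pca":
        return PCA(n_components=min(2, X.shape[1]), random_state=seed).fit(X)
    raise ValueError(f"unknown embedding {method!r}")


def _embed(embedder, X: np.ndarray) -> np.ndarray:
    return embedder.transform(X)


def extrapolate_labels(
    template_Z: np.ndarray,
    template_labels: np.ndarray,
    all_Z: np.ndarray,
    n_template_per_type: int = 500,
    k_vote: int = 100,
    embedding: str = "umap",
    seed: int | None = 0,
    return_model: bool = False,
):
    """Extend template labels to all cells via k-NN vote in a 2-D embedding.

    A template of at most ``n_template_per_type`` cells per type is drawn
    (seeded), a 2-D embedding is fitted on it, all cells are projected into
    the embedding, and each receives the modal label of its ``k_vote``
    nearest template cells.  Ties break by smallest mean neighbour distance,
    then by label sort order.
    """
    if k_vote < 1:
        raise ValueError("k_vote must be >= 1")
    template_labels = np.asarray(template_labels, dtype=object)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for t in pd.unique(template_labels):
        idx = np.flatnonzero(template_labels == t)
        if len(idx) > n_template_per_type:
            idx = rng.choice(idx, size=n_template_per_type, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    tZ, tlab = np.asarray(template_Z, dtype=float)[keep], template_labels[keep]

    if k_vote > len(tZ):
        warnings.warn(f"k_vote={k_vote} larger than template ({len(tZ)}); reduced")
        k_vote = len(tZ)

    embedder = _fit_embedder(tZ, embedding, seed)
    t_emb = _embed(embedder, tZ)
    a_emb = _embed(embedder, np.asarray(all_Z, dtype=float))

    nn = NearestNeighbors(n_neighbors=k_vote).fit(t_emb)
    dist, idx = nn.kneighbors(a_emb)
    types = np.array(sorted(pd.unique(tlab)), dtype=object)
    code_of = {t: k for k, t in enumerate(types)}
    codes = np.array([code_of[t] for t in tlab], dtype=int)
    nb_codes = codes[idx]  # (n, k_vote)

    counts = np.zeros((len(a_emb), len(types)), dtype=int)
    mean_d = np.full((len(a_emb), len(types)), np.inf)
    for c in range(len(types)):
        mask = nb_codes == c
        counts[:, c] = mask.sum(axis=1)
        with np.errstate(invalid="ignore"):
            sums = np.where(mask, dist, 0.0).sum(axis=1)
            has = counts[:, c] > 0
            mean_d[has, c] = sums[has] / counts[has, c]
    top = counts.max(axis=1)
    # tie-break: among labels at the max count, smallest mean distance; then label order
    tie_key = np.where(counts == top[:, None], mean_d, np.inf)
    winner = tie_key.argmin(axis=1)  # argmin returns first (label-order) minimum
    labels = types[winner]
    if return_model:
        return labels, {"embedder": embedder, "template_embedding": t_emb, "template_labels": tlab, "template_idx": keep}
    return labels


class ConsensusPhenotyper(BaseEstimator):
    """Consensus phenotyping estimator over a segmented-cell table.

    ``fit`` normalizes marker intensities per region, draws a stratified
    subsample, clusters it with three backends, annotates each partition
    against the signature profiles, and votes a consensus phenotype per
    subsampled cell.  ``predict`` extrapolates the voted labels to any cell
    table carrying the same marker columns via the template embedding.

    Parameters
    ----------
    markers : list of str
        Phenotypic marker columns used for clustering (the 20-marker panel
        in the reference workflow; 13 monocyte markers when subclustering).
    signatures : DataFrame
        Phenotype x marker expected profiles (numeric, or read via
        :func:`read_signatures`).
    sample_size : int
        Cells in the clustering subsample (S in the sampling equation).
    k_graph : int
        Neighbours of the Jaccard graph backend.
    min_match_r : float
        Minimum Pearson correlation for a cluster to receive a phenotype.
    n_template_per_type, k_vote : int
        Template size per type and vote size for extrapolation.
    embedding : {"umap", "pca"}
        2-D embedding for extrapolation.
    random_state : int
        Seed for sampling, clustering and embedding.

    Attributes
    ----------
    subset_index_ : Index of the clustered subsample.
    backend_labels_ : dict of per-backend phenotype labels on the subsample.
    consensus_labels_ : Series of voted labels on the subsample.
    k_ : cluster count found by the graph backend.
    """

    def __init__(
        self,
        markers=None,
        signatures=None,
        sample_size: int = 50000,
        k_graph: int = 30,
        som_shape: tuple = (10, 10),
        resolution: float = 1.0,
        min_match_r: float = 0.3,
        n_template_per_type: int = 500,
        k_vote: int = 100,
        embedding: str = "umap",
        norm_lower: float = 0.0,
        norm_upper: float = 5.0,
        group_key: str = "region_id",
        random_state: int = 0,
    ):
        self.markers = markers
        self.signatures = signatures
        self.sample_size = sample_size
        self.k_graph = k_graph
        self.som_shape = som_shape
        self.resolution = resolution
        self.min_match_r = min_match_r
        self.n_template_per_type = n_template_per_type
        self.k_vote = k_vote
        self.embedding = embedding
        self.norm_lower = norm_lower
        self.norm_upper = norm_upper
        self.group_key = group_key
        self.random_state = random_state

    # ------------------------------------------------------------------ utils
    def _zmatrix(self, cells: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
        zc = z_columns(self.markers)
        if not all(c in cells.columns for c in zc):
            cells = normalize_mfi(
                cells,
                self.markers,
                NormalizationConfig(self.norm_lower, self.norm_upper, self.group_key),
            )
        return cells, cells[zc].to_numpy(dtype=float)

    # ------------------------------------------------------------------- API
    def fit(self, cells: pd.DataFrame, y=None):
        if not self.markers:
            raise ValueError("markers must be given")
        if self.signatures is None or len(self.signatures) == 0:
            raise ValueError("signatures must be given")
        cells, _ = self._zmatrix(cells)
        total = min(self.sample_size, len(cells))
        subset, plan = stratified_sample(cells, total, seed=self.random_state)
        _, Zsub = self._zmatrix(subset)

        cfg = ClusteringConfig(
            k_graph=self.k_graph,
            som_shape=self.som_shape,
            resolution=self.resolution,
            seed=self.random_state,
        )
        partitions = run_backends(Zsub, cfg)
        self.k_ = int(partitions["graph"].max()) + 1

        sig = self.signatures.reindex(columns=self.markers)
        if sig.isna().any().any():
            raise ValueError("signatures missing some phenotypic markers")
        backend_labels = {}
        for name, part in partitions.items():
            mapping = annotate_clusters(part, Zsub, sig, self.min_match_r)
            backend_labels[name] = np.array([mapping[c] for c in part], dtype=object)
        self.backend_labels_ = backend_labels
        voted = consensus_vote(backend_labels["graph"], backend_labels["som"], backend_labels["kmeans"])
        self.subset_index_ = subset.index
        self.sampling_plan_ = plan
        self.consensus_labels_ = pd.Series(voted, index=subset.index, name="consensus")

        # template for extrapolation: voted, non-NOS subsample cells
        informative = voted != NOS
        if not informative.any():
            raise ValueError("every subsampled cell voted NOS; check signatures")
        self._template_Z = Zsub[informative]
        self._template_labels = voted[informative]
        return self

    def predict(self, cells: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "consensus_labels_"):
            raise AttributeError("fit before predict")
        cells, Z = self._zmatrix(cells)
        return extrapolate_labels(
            self._template_Z,
            self._template_labels,
            Z,
            n_template_per_type=self.n_template_per_type,
            k_vote=self.k_vote,
            embedding=self.embedding,
            seed=self.random_state,
        )

    def fit_predict(self, cells: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(cells).predict(cells)


def subcluster_myeloid(
    cells: pd.DataFrame,
    monocyte_markers: list[str],
    signatures: pd.DataFrame,
    parent_types: tuple = ("DC", "macrophage", "neutrophil"),
    label_col: str = "phenotype_consensus",
    refined_col: str = "phenotype_refined",
    **phenotyper_kwargs,
) -> pd.DataFrame:
    """Recluster the myeloid subset on monocyte-specific markers.

    Cells whose consensus label is in ``parent_types`` are re-run through
    the full normalize/cluster/annotate/vote/extrapolate chain restricted
    to the 13-marker monocyte panel; refined labels land in a separate
    column and parent labels are preserved.  Cells outside the parent set
    keep an empty refined label.
    """
    missing = [m for m in monocyte_markers if m not in cells.columns]
    if missing:
        raise KeyError(f"missing monocyte marker columns: {missing}")
    out = cells.copy()
    out[refined_col] = ""
    subset = out[out[label_col].isin(parent_types)]
    if len(subset) == 0:
        warnings.warn("empty myeloid subset; nothing reclustered")
        return out
    ph = ConsensusPhenotyper(markers=monocyte_markers, signatures=signatures, **phenotyper_kwargs)
    refined = ph.fit_predict(subset)
    out.loc[subset.index, refined_col] = refined
    return out
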
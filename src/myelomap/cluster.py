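"""Normalization, PCA reduction, SNN graph clustering, and RNA+ATAC fusion.

Clustering follows the shared-nearest-neighbor convention: kNN graph in
embedding space, edge weights by Jaccard overlap of neighbor sets, then
modularity community detection (Leiden, RB configuration model) at a
resolution parameter. Cells are re-ordered internally into a canonical
(lexicographic) order before graph construction, which makes the partition
invariant to the order cells arrive in.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .types import ClusterLabels, ExpressionMatrix

SNN_PRUNE = 1.0 / 15.0  # Jaccard weights below this are dropped (Seurat default)


@dataclass
class Embedding:
    """Cells x components matrix; rows align with ``barcodes``."""

    coords: np.ndarray
    modality: str = "RNA"
    explained_variance_ratio: np.ndarray | None = None
    loadings: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class ModalityWeights:
    w_rna: np.ndarray
    w_atac: np.ndarray

    def __post_init__(self) -> None:
        s = self.w_rna + self.w_atac
        if not np.allclose(s, 1.0):
            raise ValueError("modality weights must sum to 1 per cell")


def normalize_log_cp10k(matrix: ExpressionMatrix) -> sp.csr_matrix:
    """ln(1 + 10000 * count / cell_total), sparse.

    Cells with zero total must have been removed by QC beforehand.
    """
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError(
            "cell with zero total counts; run QC filtering before normalization"
        )
    x = sp.csr_matrix(matrix.counts, dtype=float)
    scale = 10_000.0 / totals
    x = sp.diags(scale) @ x
    x.data = np.log1p(x.data)
    return sp.csr_matrix(x)


def select_variable_features(normalized: sp.csr_matrix, n_top: int = 2000) -> np.ndarray:
    """Indices of the n_top features by variance of normalized values."""
    x = normalized
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = sq - mean**2
    n_top = min(n_top, x.shape[1])
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:n_top])


def reduce(
    normalized: sp.csr_matrix | np.ndarray,
    n_components: int = 30,
    seed: int = 0,
    modality: str = "RNA",
) -> Embedding:
    """PCA embedding with a fixed sign convention.

    Components are ordered by decreasing explained variance; each
    component's sign is fixed by forcing its largest-magnitude loading
    positive, so repeated runs agree exactly.
    """
    x = normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized)
    if n_components >= min(x.shape):
        raise ValueError(
            f"n_components={n_components} must be < min(cells, features)={min(x.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(x)
    loadings = pca.components_.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            coords[:, k] *= -1.0
    return Embedding(
        coords,
        modality,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
    )


# ---------------------------------------------------------------------------
# graph construction


def _canonical_order(coords: np.ndarray) -> np.ndarray:
    """Permutation-invariant cell ordering: lexicographic on coordinates."""
    return np.lexsort(coords.T[::-1])


def _knn_indicator(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Binary cells x cells matrix of k nearest neighbors (self included)."""
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k, algorithm="auto").fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    rows = np.repeat(np.arange(n), k)
    data = np.ones(n * k)
    a = sp.csr_matrix((data, (rows, idx.ravel())), shape=(n, n))
    a = a.maximum(sp.eye(n, format="csr"))  # ensure self-membership
    return sp.csr_matrix(a)


def snn_graph(coords: np.ndarray, k_neighbors: int, prune: float = SNN_PRUNE) -> sp.csr_matrix:
    """SNN affinity: Jaccard overlap of kNN sets, pruned below ``prune``."""
    a = _knn_indicator(coords, k_neighbors)
    inter = (a @ a.T).tocoo()
    sizes = np.asarray(a.sum(axis=1)).ravel()
    union = sizes[inter.row] + sizes[inter.col] - inter.data
    jac = inter.data / union
    keep = (jac >= prune) & (inter.row != inter.col)
    g = sp.csr_matrix(
        (jac[keep], (inter.row[keep], inter.col[keep])), shape=a.shape
    )
    return sp.csr_matrix((g + g.T) / 2.0)


def cluster_graph(
    affinity: sp.spmatrix, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on a weighted affinity graph."""
    coo = sp.triu(sp.coo_matrix(affinity), k=1)
    edges = list(zip(coo.row.tolist(), coo.col.tolist()))
    g = ig.Graph(n=affinity.shape[0], edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(),
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def _relabel_contiguous(labels: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Relabel so ids appear contiguously in canonical order (deterministic)."""
    mapping: dict[int, int] = {}
    for i in order:
        c = int(labels[i])
        if c not in mapping:
            mapping[c] = len(mapping)
    return np.array([mapping[int(c)] for c in labels], dtype=int)


def snn_cluster(
    embedding: Embedding | np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterLabels:
    """SNN graph + Leiden communities; invariant to cell ordering."""
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    order = _canonical_order(coords)
    inv = np.argsort(order)
    graph = snn_graph(coords[order], k_neighbors)
    lab_canon = cluster_graph(graph, resolution, seed)
    labels = lab_canon[inv]
    labels = _relabel_contiguous(labels, order)
    return ClusterLabels(labels, resolution, seed)


# ---------------------------------------------------------------------------
# modality fusion


def _neighbor_prediction_distance(coords: np.ndarray, k: int) -> np.ndarray:
    """Distance between each cell and the mean of its k nearest neighbors
    (self excluded), on unit-total-variance coordinates."""
    x = coords / np.sqrt(np.maximum(coords.var(axis=0).sum(), 1e-12))
    n = x.shape[0]
    if k + 1 > n:
        raise ValueError("k_neighbors too large for modality fusion")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    idx = nn.kneighbors(x, return_distance=False)[:, 1:]
    pred = x[idx].mean(axis=1)
    return np.linalg.norm(x - pred, axis=1)


def fuse_modalities(
    emb_rna: Embedding,
    emb_atac: Embedding,
    mode: str = "equal",
    k_neighbors: int = 20,
) -> tuple[sp.csr_matrix, ModalityWeights]:
    """Weighted fusion of the two modality SNN graphs.

    mode "equal": both modalities weighted 0.5 for every cell.
    mode "wnn": per-cell weights from a softmax of each modality's
    within-modality neighborhood prediction accuracy (cells whose profile
    is well predicted by its neighbors in a modality trust that modality
    more). The fused affinity is the per-edge weighted mean of the two SNN
    Jaccard graphs.
    """
    if emb_rna.coords.shape[0] != emb_atac.coords.shape[0]:
        raise ValueError("modalities must share barcode order (cell count mismatch)")
    n = emb_rna.coords.shape[0]
    if mode == "equal":
        w_rna = np.full(n, 0.5)
    elif mode == "wnn":
        d_rna = _neighbor_prediction_distance(emb_rna.coords, k_neighbors)
        d_atac = _neighbor_prediction_distance(emb_atac.coords, k_neighbors)
        tau = np.maximum((d_rna + d_atac) / 2.0, 1e-12)
        a = np.exp(-d_rna / tau)
        b = np.exp(-d_atac / tau)
        w_rna = a / (a + b)
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    w_atac = 1.0 - w_rna

    g_rna = snn_graph(emb_rna.coords, k_neighbors)
    g_atac = snn_graph(emb_atac.coords, k_neighbors)
    wr = sp.diags(w_rna)
    wa = sp.diags(w_atac)
    fused = (wr @ g_rna + g_rna @ wr) / 2.0 + (wa @ g_atac + g_atac @ wa) / 2.0
    return sp.csr_matrix(fused), ModalityWeights(w_rna, w_atac)


def joint_cluster(
    emb_rna: Embedding,
    emb_atac: Embedding,
    mode: str = "equal",
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[ClusterLabels, ModalityWeights]:
    """Fuse the two modalities and cluster the fused graph.

    Cells are canonically ordered on the concatenated embeddings before
    graph construction, as in :func:`snn_cluster`.
    """
    joint = np.hstack([emb_rna.coords, emb_atac.coords])
    order = _canonical_order(joint)
    inv = np.argsort(order)
    emb_r = Embedding(emb_rna.coords[order], emb_rna.modality)
    emb_a = Embedding(emb_atac.coords[order], emb_atac.modality)
    fused, weights = fuse_modalities(emb_r, emb_a, mode, k_neighbors)
    lab_canon = cluster_graph(fused, resolution, seed)
    labels = _relabel_contiguous(lab_canon[inv], order)
    return (
        ClusterLabels(labels, resolution, seed),
        ModalityWeights(weights.w_rna[inv], weights.w_atac[inv]),
    )
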
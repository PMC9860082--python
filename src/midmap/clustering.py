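"""Graph clustering of cells: PCA, exact kNN graph, Louvain communities.

The clustering substrate mirrors the Cytograph-style recipe used for
scRNA-seq: principal components of the normalized feature submatrix, a
mutualized k-nearest-neighbor graph, and Louvain modularity
optimization.  Every tie is broken by lowest cell index so that results
are reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocess import FeatureSet, _dense

__all__ = [
    "Embedding",
    "NeighborGraph",
    "ClusterPartition",
    "CompositionTable",
    "reduce_dimensions",
    "build_knn_graph",
    "louvain_cluster",
    "report_composition",
]


@dataclass
class Embedding:
    """Cells x d principal-component coordinates."""

    coords: np.ndarray
    method: str
    d: int
    feature_genes: tuple[str, ...]
    explained_variance: np.ndarray = field(repr=False)
    cell_ids: tuple[str, ...] = ()

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class NeighborGraph:
    """Undirected kNN graph over cells (edge if either direction is a kNN)."""

    graph: nx.Graph
    k: int
    metric: str

    @property
    def n_cells(self) -> int:
        return self.graph.number_of_nodes()

    def edge_list(self) -> pd.DataFrame:
        rows = [(u, v, d.get("weight", 1.0)) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["cell_i", "cell_j", "weight"])


@dataclass
class ClusterPartition:
    """Per-cell cluster labels, contiguous 0..n_clusters-1."""

    labels: np.ndarray
    n_clusters: int
    modularity: float
    resolution: float
    seed: int
    cell_ids: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        ids = self.cell_ids or [str(i) for i in range(len(self.labels))]
        return pd.DataFrame({"cell_id": list(ids), "cluster": self.labels})


def reduce_dimensions(
    norm: ad.AnnData, features: FeatureSet, d: int, seed: int = 0
) -> Embedding:
    """PCA on the centered feature submatrix.

    Components are ordered by decreasing explained variance; each
    component's sign is fixed so its largest-magnitude gene loading is
    positive, making the embedding deterministic.
    """
    genes = [g for g in features]
    missing = [g for g in genes if g not in norm.var_names]
    if missing:
        raise ValueError(f"features absent from matrix: {missing[:5]}")
    if d < 2:
        raise ValueError("d must be >= 2")
    if d > min(norm.n_obs, len(genes)):
        raise ValueError(
            f"d={d} exceeds min(n_cells={norm.n_obs}, n_features={len(genes)})"
        )
    X = _dense(norm[:, genes].X)
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(X)
    flip = np.sign(
        pca.components_[np.arange(d), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    coords = coords * flip[None, :]
    return Embedding(
        coords=coords,
        method="pca",
        d=d,
        feature_genes=tuple(genes),
        explained_variance=pca.explained_variance_.copy(),
        cell_ids=tuple(norm.obs_names),
    )


def _knn_edges(coords: np.ndarray, k: int, chunk: int = 512) -> set[tuple[int, int]]:
    n = coords.shape[0]
    edges: set[tuple[int, int]] = set()
    sq = (coords**2).sum(axis=1)
    idx = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = coords[start:stop]
        d2 = sq[start:stop, None] - 2.0 * block @ coords.T + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        for row, i in enumerate(range(start, stop)):
            di = d2[row].copy()
            di[i] = np.inf  # no self-loops
            # ties broken by lowest cell index
            order = np.lexsort((idx, di))[:k]
            for j in order:
                edges.add((min(i, int(j)), max(i, int(j))))
    return edges


def build_knn_graph(emb: Embedding, k: int, metric: str = "euclidean") -> NeighborGraph:
    """Mutualized exact kNN graph (unit edge weights, no self-loops)."""
    if metric != "euclidean":
        raise ValueError(f"unsupported metric: {metric!r}")
    n = emb.n_cells
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells={n}")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(_knn_edges(emb.coords, k), weight=1.0)
    return NeighborGraph(graph=g, k=k, metric=metric)


def louvain_cluster(
    g: NeighborGraph, resolution: float = 1.0, seed: int = 0
) -> ClusterPartition:
    """Louvain community detection on the kNN graph.

    Greedy modularity optimization (local moves until no gain, then
    graph aggregation, repeated); deterministic given the seed.
    Communities are relabeled 0..n_clusters-1 in order of their lowest
    member index.  A graph with no edges yields singletons with
    modularity 0.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    graph = g.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if graph.number_of_edges() == 0:
        labels = np.arange(graph.number_of_nodes())
        return ClusterPartition(labels, len(labels), 0.0, resolution, seed)
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=min)
    labels = np.empty(graph.number_of_nodes(), dtype=int)
    for c, members in enumerate(comms):
        labels[list(members)] = c
    q = nx.community.modularity(graph, comms, weight="weight", resolution=resolution)
    return ClusterPartition(
        labels=labels,
        n_clusters=len(comms),
        modularity=float(q),
        resolution=resolution,
        seed=seed,
    )


@dataclass
class CompositionTable:
    """Per-cluster counts and row-normalized proportions over a categorical."""

    counts: pd.DataFrame
    proportions: pd.DataFrame

    def max_imbalance(self) -> float:
        """Largest deviation of any per-cluster proportion from the
        global proportion of its category."""
        global_prop = self.counts.sum(axis=0) / self.counts.values.sum()
        return float((self.proportions - global_prop).abs().values.max())


def report_composition(
    partition: ClusterPartition, metadata: pd.Series
) -> CompositionTable:
    """Cross-tabulate cluster membership against a per-cell categorical
    (line, time point, ...)."""
    if len(metadata) != len(partition.labels):
        raise ValueError(
            f"metadata length {len(metadata)} != n_cells {len(partition.labels)}"
        )
    counts = pd.crosstab(
        pd.Series(partition.labels, name="cluster"),
        pd.Series(np.asarray(metadata), name=metadata.name or "category"),
    )
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return CompositionTable(counts=counts, proportions=proportions)
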
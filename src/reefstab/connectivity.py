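"""Metacommunity network diagnostics.

Sites become nodes of two complete distance graphs — geographic (sea
distances, or great-circle as fallback) and biological (Jaccard
compositional dissimilarity) — reduced to minimum spanning trees.  Weighted
degree (sum of inverse-distance edge weights) and closeness (reciprocal
mean along-tree distance) centralities characterise local and global
connectivity; regressing biological degree on geographic closeness tests
whether geographically central sites are also compositional hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpatialGraph",
    "jaccard_matrix",
    "haversine_matrix",
    "minimum_spanning_tree",
    "degree_centrality",
    "closeness_centrality",
    "centrality_regression",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class SpatialGraph:
    """A distance-weighted site graph (typically an MST)."""

    nodes: list[str]
    graph: nx.Graph
    kind: str  # "geographic" or "biological"

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["distance"]) for u, v, d in self.graph.edges(data=True)]

    def total_weight(self) -> float:
        return float(sum(d for _, _, d in self.edges()))


def jaccard_matrix(presence: pd.DataFrame) -> np.ndarray:
    """Pairwise Jaccard dissimilarity (1 - |A∩B|/|A∪B|) between site rows.

    ``presence`` is a site x species incidence table (nonzero = present).
    """
    inc = (presence.to_numpy() > 0).astype(float)
    if (inc.sum(axis=1) == 0).any():
        empty = presence.index[inc.sum(axis=1) == 0].tolist()
        raise ValueError(f"site(s) with no species: {empty}")
    inter = inc @ inc.T
    sizes = inc.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return d


def haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) from decimal-degree coordinates."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def minimum_spanning_tree(
    distances: np.ndarray, nodes: list[str] | None = None, kind: str = "geographic"
) -> SpatialGraph:
    """Minimum spanning tree of a complete symmetric distance matrix.

    Ties are broken deterministically by lexicographic node-pair order
    (edges are inserted in that order and Kruskal's sort is stable).
    """
    d = np.asarray(distances, dtype=float)
    if not np.all(np.isfinite(d[~np.eye(len(d), dtype=bool)])):
        raise ValueError("distances must be finite")
    n = d.shape[0]
    if nodes is None:
        nodes = [f"n{i}" for i in range(n)]
    order = sorted(range(n), key=lambda i: str(nodes[i]))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a in range(n):
        for b in range(a + 1, n):
            i, j = order[a], order[b]
            g.add_edge(nodes[i], nodes[j], distance=float(d[i, j]))
    mst = nx.minimum_spanning_tree(g, weight="distance", algorithm="kruskal")
    return SpatialGraph(list(nodes), mst, kind)


def degree_centrality(graph: SpatialGraph, scaled: bool = False) -> pd.Series:
    """Weighted degree: sum of 1/distance over a node's incident edges."""
    vals = {
        node: sum(1.0 / d["distance"] for _, _, d in graph.graph.edges(node, data=True))
        for node in graph.nodes
    }
    s = pd.Series(vals, name="degree")
    return _zscore(s) if scaled else s


def closeness_centrality(
    graph: SpatialGraph, scaled: bool = False, length: str = "distance"
) -> pd.Series:
    """Closeness: reciprocal of the mean shortest-path distance to all others.

    ``length="distance"`` (default) uses edge lengths equal to the distances,
    so "close" means geographically near; ``length="inverse"`` reproduces the
    affinity-as-length variant (edge length = 1/distance) for comparison.
    """
    g = graph.graph
    if not nx.is_connected(g):
        raise ValueError("closeness requires a connected graph")

    def edge_len(u, v, d):
        return d["distance"] if length == "distance" else 1.0 / d["distance"]

    vals = {}
    for node in graph.nodes:
        dist = nx.single_source_dijkstra_path_length(g, node, weight=edge_len)
        others = [dist[m] for m in graph.nodes if m != node]
        vals[node] = 1.0 / np.mean(others) if others else float("nan")
    s = pd.Series(vals, name="closeness")
    return _zscore(s) if scaled else s


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{s.name} has zero variance; cannot scale")
    return (s - s.mean()) / sd


def centrality_regression(
    closeness_geo: pd.Series, degree_bio: pd.Series
) -> tuple[float, float, float]:
    """OLS of scaled biological degree on scaled geographic closeness.

    Returns (slope, intercept, two-sided p-value of the slope).  Both
    centralities are z-scored over the matched node set first.
    """
    idx = closeness_geo.index.intersection(degree_bio.index)
    if len(idx) < 3:
        raise ValueError("need at least 3 matched nodes")
    x = _zscore(closeness_geo.loc[idx])
    y = _zscore(degree_bio.loc[idx])
    fit = stats.linregress(x.to_numpy(), y.to_numpy())
    return float(fit.slope), float(fit.intercept), float(fit.pvalue)
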
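"""Repertoire-level (global) network properties of a similarity layer.

All graphs here are Boolean and undirected.  The metrics follow the standard
definitions: order N, size L, average degree <k> = 2L/N, density, global
clustering coefficient (transitivity, triangles over connected triples),
diameter of the largest component, Freeman degree centralization, and degree
assortativity (the Pearson correlation of the degrees at the two ends of an
edge).

Assortativity is reported as ``None`` (undefined), not zero, when the degree
variance over edge ends vanishes — e.g. on regular graphs — since the
correlation is then 0/0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

from .distance import SimilarityLayer, degrees_from_edges


@dataclass
class ComponentDecomposition:
    labels: np.ndarray          # component label per node
    sizes: np.ndarray           # size per component label
    n_components: int
    largest_label: int

    @property
    def largest_size(self) -> int:
        return int(self.sizes[self.largest_label])

    def largest_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.labels == self.largest_label)


@dataclass
class GlobalMetrics:
    """One row of the global characterization of a similarity layer."""

    N: int
    L: int
    avg_degree: float
    density: float
    diameter: int | None
    largest_component_size: int
    largest_component_fraction: float
    n_components: int
    component_sizes: list[int]
    clustering_coefficient: float   # transitivity: 3*triangles / triples
    avg_local_clustering: float     # mean of local C_j (isolated/deg-1 -> 0)
    centralization: float | None    # Freeman degree centralization
    assortativity: float | None     # None when undefined (sigma_q^2 = 0)

    def to_dict(self) -> dict:
        return asdict(self)


def _adjacency(edges: np.ndarray, n: int) -> sp.csr_matrix:
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.size == 0:
        return sp.csr_matrix((n, n), dtype=np.int8)
    data = np.ones(len(edges) * 2, dtype=np.int8)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def connected_components(layer: SimilarityLayer, n_nodes: int | None = None) -> ComponentDecomposition:
    """Label every node with its connected component; sizes sum to N."""
    n = layer.n_nodes if n_nodes is None else n_nodes
    adj = _adjacency(layer.edges, n)
    n_comp, labels = _cc(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return ComponentDecomposition(
        labels=labels,
        sizes=sizes,
        n_components=int(n_comp),
        largest_label=int(np.argmax(sizes)),
    )


def _bfs_eccentricity(adj_lists: list[np.ndarray], source: int, member: np.ndarray) -> int:
    """Eccentricity of ``source`` within its component (edge-count geodesics)."""
    n = len(adj_lists)
    dist = np.full(n, -1, dtype=np.int64)
    dist[source] = 0
    frontier = [source]
    ecc = 0
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj_lists[u]:
                if dist[v] < 0 and member[v]:
                    dist[v] = dist[u] + 1
                    ecc = max(ecc, int(dist[v]))
                    nxt.append(v)
        frontier = nxt
    return ecc


def diameter_of_largest_component(layer: SimilarityLayer) -> tuple[int | None, np.ndarray]:
    """Diameter (longest geodesic, counted in edges) of the largest component.

    Returns (diameter, nodes of that component).  ``None`` for an edgeless
    graph.  Computed by BFS from every node of the component.
    """
    comps = connected_components(layer)
    nodes = comps.largest_nodes()
    if layer.n_edges == 0 or len(nodes) < 2:
        return (0 if len(nodes) >= 1 and layer.n_edges > 0 else None), nodes
    member = np.zeros(layer.n_nodes, dtype=bool)
    member[nodes] = True
    adj = _adjacency(layer.edges, layer.n_nodes)
    adj_lists = [adj.indices[adj.indptr[i]: adj.indptr[i + 1]] for i in range(layer.n_nodes)]
    return max(_bfs_eccentricity(adj_lists, int(s), member) for s in nodes), nodes


def _triangles_and_triples(adj: sp.csr_matrix, degrees: np.ndarray) -> tuple[float, float]:
    """(number of triangles, number of connected triples)."""
    if adj.nnz == 0:
        return 0.0, 0.0
    a = adj.astype(np.int64)
    tri = (a @ a).multiply(a).sum() / 6.0
    triples = float((degrees * (degrees - 1)).sum() / 2.0)
    return float(tri), triples


def local_clustering(edges: np.ndarray, n: int) -> np.ndarray:
    """Local clustering coefficient C_j = 2 e_j / (k_j (k_j - 1)); 0 where
    the degree is below 2 (undefined cases, documented convention)."""
    adj = _adjacency(edges, n).astype(np.int64)
    deg = degrees_from_edges(edges, n).astype(float)
    if adj.nnz == 0:
        return np.zeros(n)
    tri2 = (adj @ adj).multiply(adj).sum(axis=1).A1  # 2x triangles through j
    denom = deg * (deg - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c


def degree_centralization(degrees: np.ndarray) -> float | None:
    """Freeman degree centralization, normalized by the star-graph maximum
    (N-1)(N-2).  Undefined (None) for N < 3."""
    n = len(degrees)
    if n < 3:
        return None
    kmax = degrees.max()
    return float((kmax - degrees).sum() / ((n - 1) * (n - 2)))


def assortativity(edges: np.ndarray, degrees: np.ndarray) -> float | None:
    """Degree assortativity r: Pearson correlation of the degrees at either
    end of an edge, both edge orientations included.  ``None`` when the
    edge-end degree variance is zero (r undefined, e.g. regular graphs)."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if len(edges) == 0:
        return None
    x = np.concatenate([degrees[edges[:, 0]], degrees[edges[:, 1]]]).astype(float)
    y = np.concatenate([degrees[edges[:, 1]], degrees[edges[:, 0]]]).astype(float)
    vx = x.var()
    if vx == 0:
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / vx)


def assortativity_from_joint_distribution(edges: np.ndarray, degrees: np.ndarray) -> float | None:
    """Assortativity via the remaining-degree joint distribution e_jk:

        r = (1 / sigma_q^2) * sum_jk j k (e_jk - q_j q_k)

    where q_k is the marginal remaining-degree distribution over edge ends
    and sigma_q^2 its variance.  Equivalent to the edge-end Pearson form;
    kept as an independent formulation (cross-checked in the test suite).
    """
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if len(edges) == 0:
        return None
    ends_j = degrees[edges[:, 0]] - 1  # remaining degrees
    ends_k = degrees[edges[:, 1]] - 1
    e_jk: Counter[tuple[int, int]] = Counter()
    for j, k in zip(ends_j.tolist(), ends_k.tolist()):
        e_jk[(j, k)] += 1
        e_jk[(k, j)] += 1
    total = sum(e_jk.values())
    q: Counter[int] = Counter()
    for (j, _k), w in e_jk.items():
        q[j] += w
    qdist = {j: w / total for j, w in q.items()}
    mean_q = sum(j * p for j, p in qdist.items())
    var_q = sum((j - mean_q) ** 2 * p for j, p in qdist.items())
    if var_q == 0:
        return None
    # sum_jk jk e_jk minus sum_jk jk q_j q_k; the latter factorizes to mean_q^2
    s = sum(j * k * w / total for (j, k), w in e_jk.items()) - mean_q**2
    return float(s / var_q)


def global_metrics(layer: SimilarityLayer, n_nodes: int | None = None) -> GlobalMetrics:
    """Compute every global property of one similarity layer.

    The diameter is that of the largest connected component (the graphs are
    typically disconnected); assortativity and centralization carry explicit
    ``None`` markers when undefined.
    """
    n = layer.n_nodes if n_nodes is None else n_nodes
    if n < 1:
        raise ValueError("graph must have at least one node")
    edges = layer.edges
    L = layer.n_edges
    deg = degrees_from_edges(edges, n)
    comps = connected_components(layer, n)
    diam, _ = diameter_of_largest_component(layer)
    adj = _adjacency(edges, n)
    tri, triples = _triangles_and_triples(adj, deg)
    transitivity = 3.0 * tri / triples if triples > 0 else 0.0
    return GlobalMetrics(
        N=n,
        L=L,
        avg_degree=2.0 * L / n,
        density=(2.0 * L / (n * (n - 1))) if n > 1 else 0.0,
        diameter=diam,
        largest_component_size=comps.largest_size,
        largest_component_fraction=comps.largest_size / n,
        n_components=comps.n_components,
        component_sizes=sorted(comps.sizes.tolist(), reverse=True),
        clustering_coefficient=transitivity,
        avg_local_clustering=float(local_clustering(edges, n).mean()),
        centralization=degree_centralization(deg),
        assortativity=assortativity(edges, deg),
    )
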
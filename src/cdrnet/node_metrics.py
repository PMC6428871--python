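"""Clone-level (local) network properties.

Centralities quantify how "important" a clone is inside the similarity
architecture: degree counts its immediate sequence neighbours, eigenvector /
authority weight neighbours by their own importance, PageRank adds a
teleport process, closeness measures how few edits separate a clone from the
rest of its component, and betweenness counts the geodesics brokered by a
clone.  Coreness locates each clone in the k-core hierarchy; the maximal
core is the innermost, most densely interconnected region of the repertoire.

Conventions (documented, matching the degenerate-input contract):

* isolated nodes: degree 0, closeness 0, betweenness 0, local clustering 0;
* eigenvector and authority are rescaled to maximum entry 1 and resolved to
  non-negative vectors; an edgeless graph yields all-zero vectors;
* closeness is computed within components and normalized by
  (component size - 1), so it lies in [0, 1];
* betweenness is unnormalized;
* PageRank uses teleport probability alpha = 0.85 unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .distance import SimilarityLayer, degrees_from_edges
from .graph_metrics import _adjacency, connected_components, local_clustering
from .repertoire import Repertoire


@dataclass
class NodeMetrics:
    """Per-clone metric vectors, all of length n_nodes."""

    degree: np.ndarray
    transitivity: np.ndarray      # local clustering C_j
    eigenvector: np.ndarray
    authority: np.ndarray
    pagerank: np.ndarray
    closeness: np.ndarray         # normalized within components
    betweenness: np.ndarray       # unnormalized
    coreness: np.ndarray
    alpha: float = 0.85

    def to_frame(self, sequences: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "degree": self.degree,
                "transitivity": self.transitivity,
                "eigenvector": self.eigenvector,
                "authority": self.authority,
                "pagerank": self.pagerank,
                "closeness": self.closeness,
                "betweenness": self.betweenness,
                "coreness": self.coreness,
            }
        )
        if sequences is not None:
            df.insert(0, "cdr3_aa", sequences)
        return df


def power_iteration_centrality(
    adj: sp.csr_matrix,
    squared: bool = False,
    tol: float = 1e-13,
    max_iter: int = 1_000_000,
) -> np.ndarray:
    """Principal-eigenvector centrality by power iteration.

    ``squared=False`` iterates A x (eigenvector centrality); ``squared=True``
    iterates A^T A x (authority — identical direction on undirected graphs).
    The result is non-negative and rescaled so its maximum entry is 1.
    Converges when the max-norm change falls below ``tol``.
    """
    n = adj.shape[0]
    if adj.nnz == 0:
        return np.zeros(n)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        # iterate (A + I) x: same eigenvectors, but the spectral shift breaks
        # the +/-lambda oscillation of bipartite components
        y = adj @ x + x
        if squared:
            y = adj.T @ y + y
        norm = np.linalg.norm(y)
        if norm == 0:  # pragma: no cover - nnz>0 with uniform start
            return np.zeros(n)
        y /= norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    return x / x.max()


def centralities(
    layer: SimilarityLayer,
    n_nodes: int | None = None,
    alpha: float = 0.85,
    tol: float = 1e-13,
) -> NodeMetrics:
    """All eight per-clone metrics of one similarity layer."""
    n = layer.n_nodes if n_nodes is None else n_nodes
    if n < 1:
        raise ValueError("graph must have at least one node")
    edges = layer.edges
    adj = _adjacency(edges, n).astype(float)
    g = layer.to_networkx()

    deg = degrees_from_edges(edges, n)
    eig = power_iteration_centrality(adj, squared=False, tol=tol)
    auth = power_iteration_centrality(adj, squared=True, tol=tol)

    if layer.n_edges == 0:
        pr = np.full(n, 1.0 / n)
    else:
        pr_dict = nx.pagerank(g, alpha=alpha, tol=1e-13, max_iter=1000)
        pr = np.array([pr_dict[i] for i in range(n)])

    clo_dict = nx.closeness_centrality(g, wf_improved=False)
    clo = np.array([clo_dict[i] for i in range(n)])
    bet_dict = nx.betweenness_centrality(g, normalized=False)
    bet = np.array([bet_dict[i] for i in range(n)])
    core_dict = nx.core_number(g)
    core = np.array([core_dict[i] for i in range(n)], dtype=np.int64)

    return NodeMetrics(
        degree=deg,
        transitivity=local_clustering(edges, n),
        eigenvector=eig,
        authority=auth,
        pagerank=pr,
        closeness=clo,
        betweenness=bet,
        coreness=core,
        alpha=alpha,
    )


@dataclass
class KCoreResult:
    coreness: np.ndarray
    k_max: int
    maximal_core_nodes: np.ndarray
    maximal_core_fraction: float      # % of clones composing the maximal core
    core_sizes: dict[int, int] = field(default_factory=dict)  # k -> |k-core|


def kcore_decomposition(layer: SimilarityLayer, n_nodes: int | None = None) -> KCoreResult:
    """Coreness per clone, the maximal (innermost) core, and the k-core size
    distribution along k.

    The k-core is the maximal subgraph where every node has degree >= k; a
    node's coreness is the largest k whose core contains it.
    """
    n = layer.n_nodes if n_nodes is None else n_nodes
    g = layer.to_networkx()
    core_dict = nx.core_number(g)
    coreness = np.array([core_dict[i] for i in range(n)], dtype=np.int64)
    k_max = int(coreness.max()) if n else 0
    core_sizes = {k: int((coreness >= k).sum()) for k in range(1, k_max + 1)}
    maximal = np.flatnonzero(coreness == k_max)
    return KCoreResult(
        coreness=coreness,
        k_max=k_max,
        maximal_core_nodes=maximal,
        maximal_core_fraction=100.0 * len(maximal) / n if n else 0.0,
        core_sizes=core_sizes,
    )


def neighborhood_sizes(
    layer: SimilarityLayer,
    orders: list[int],
    n_nodes: int | None = None,
    include_focal: bool = False,
) -> dict[int, float]:
    """Mean normalized neighborhood size per order.

    For each clone, count the distinct clones within geodesic distance
    <= order (excluding the focal clone unless ``include_focal``), divide by
    N, then average over clones.  Non-decreasing in the order and plateaus at
    (component size - 1)/N once the order reaches the component diameter.
    """
    if any(o < 1 for o in orders):
        raise ValueError("orders must be >= 1")
    n = layer.n_nodes if n_nodes is None else n_nodes
    g = layer.to_networkx()
    orders = sorted(set(orders))
    sums = {o: 0.0 for o in orders}
    for v in range(n):
        dist = nx.single_source_shortest_path_length(g, v, cutoff=max(orders))
        dvals = np.array(sorted(dist.values()))
        for o in orders:
            cnt = int((dvals <= o).sum())
            if not include_focal:
                cnt -= 1
            sums[o] += cnt / n
    return {o: sums[o] / n for o in orders}


class CliqueGuardError(RuntimeError):
    """Raised when the graph exceeds the clique-search size guard."""


def largest_clique(
    layer: SimilarityLayer,
    n_nodes: int | None = None,
    max_nodes: int = 5000,
) -> tuple[int, list[int]]:
    """Maximum clique cardinality and one witness member set.

    Worst case is exponential; graphs with more than ``max_nodes`` nodes are
    refused with :class:`CliqueGuardError` rather than silently hanging.
    """
    n = layer.n_nodes if n_nodes is None else n_nodes
    if n > max_nodes:
        raise CliqueGuardError(
            f"clique search not computed: {n} nodes exceeds guard ({max_nodes})"
        )
    g = layer.to_networkx()
    clique, _ = nx.max_weight_clique(g, weight=None)
    if not clique:  # empty graph: every single node is a 1-clique
        clique = [0] if n else []
    return len(clique), sorted(clique)


@dataclass
class CohortVariation:
    """Cross-sample relative variability of one metric."""

    metric: str
    values: np.ndarray           # per-sample mean values
    cv: float | None             # (sd / mean) * 100, None when mean == 0


def cohort_cv(values, metric: str = "") -> CohortVariation:
    """Coefficient of variation CV = (sd / mean) * 100 across sample means.

    Uses the sample standard deviation (ddof=1).  Scale-invariant; undefined
    (None) when the mean is zero.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 samples")
    mean = arr.mean()
    if mean == 0:
        return CohortVariation(metric=metric, values=arr, cv=None)
    return CohortVariation(metric=metric, values=arr, cv=float(arr.std(ddof=1) / mean * 100.0))


def metric_frequency_correlation(
    metrics: NodeMetrics, rep: Repertoire, which: str
) -> float | None:
    """Pearson correlation between a per-clone metric and clone frequency.

    ``None`` when either vector is constant (correlation undefined).
    """
    vec = np.asarray(getattr(metrics, which), dtype=float)
    freq = rep.frequencies
    if len(vec) != len(freq):
        raise ValueError("metric vector and repertoire size mismatch")
    if len(vec) < 3:
        raise ValueError("correlation requires at least 3 clones")
    if vec.std() == 0 or freq.std() == 0:
        return None
    return float(np.corrcoef(vec, freq)[0, 1])
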
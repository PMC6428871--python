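"""Levenshtein similarity layers over CDR3 clones.

The similarity structure of a repertoire is encoded as a set of Boolean
undirected graphs ("similarity layers"): in the *exact* layer ``LD_n`` two
clones are adjacent iff their Levenshtein distance equals ``n``; in the
*cumulative* layer ``LD_<=n`` they are adjacent iff ``1 <= LD <= n``.  Only
the upper triangle (i < j) of the pairwise distance matrix is evaluated, and
distances above ``max_ld`` are never stored, so the representation stays
sparse even for large repertoires.

Edit distances are computed with edlib, banded at ``max_ld`` (pairs further
apart than the band are reported as "beyond cutoff" without full evaluation,
which is exact for every distance we keep).  A pair whose length difference
exceeds ``max_ld`` cannot be within the band and is pruned before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import edlib
import numpy as np

from .repertoire import Repertoire, validate_sequence

Mode = Literal["exact", "cumulative"]

MAX_SUPPORTED_LD = 12


def levenshtein(a: str, b: str) -> int:
    """Standard (unit-cost) edit distance between two amino-acid strings.

    Symmetric, zero iff the strings are equal; lengths may differ.
    """
    a = validate_sequence(a)
    b = validate_sequence(b)
    return int(edlib.align(a, b, task="distance")["editDistance"])


def _banded_distance(a: str, b: str, cutoff: int) -> int:
    """Edit distance if <= cutoff, else -1 (edlib band semantics)."""
    return int(edlib.align(a, b, task="distance", k=cutoff)["editDistance"])


@dataclass(frozen=True)
class SimilarityLayer:
    """One Boolean undirected similarity graph over indexed clones."""

    n: int
    mode: Mode
    edges: np.ndarray  # (m, 2) int64, i < j, unique rows
    n_nodes: int

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size and not (e[:, 0] < e[:, 1]).all():
            raise ValueError("edges must satisfy i < j")
        object.__setattr__(self, "edges", e)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def degrees(self) -> np.ndarray:
        """Per-clone degree vector k_i (length n_nodes)."""
        return degrees_from_edges(self.edges, self.n_nodes)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges.tolist()))
        return g


def degrees_from_edges(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    deg = np.zeros(n_nodes, dtype=np.int64)
    if edges.size:
        deg += np.bincount(edges[:, 0], minlength=n_nodes)
        deg += np.bincount(edges[:, 1], minlength=n_nodes)
    return deg


def _canonical_edge_order(ii, jj, dd):
    ii = np.asarray(ii, dtype=np.int64)
    jj = np.asarray(jj, dtype=np.int64)
    dd = np.asarray(dd, dtype=np.int64)
    order = np.lexsort((jj, ii))
    return ii[order], jj[order], dd[order]


@dataclass
class LayeredNetwork:
    """All similarity layers 1..max_ld of one repertoire.

    ``clone_index`` maps node index -> cdr3_aa in repertoire order; the
    sparse triangle of distances <= max_ld is stored once as parallel arrays
    (src, dst, ld) from which any exact or cumulative layer is a view.
    """

    sequences: list[str]
    max_ld: int
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_ld: np.ndarray
    counts: np.ndarray | None = None
    v_genes: list[str | None] | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.edge_src, self.edge_dst, self.edge_ld = _canonical_edge_order(
            self.edge_src, self.edge_dst, self.edge_ld
        )

    @property
    def n_nodes(self) -> int:
        return len(self.sequences)

    @property
    def clone_index(self) -> dict[int, str]:
        return dict(enumerate(self.sequences))

    def _check_layer(self, n: int) -> None:
        if not 1 <= n <= self.max_ld:
            raise ValueError(f"layer {n} outside computed range 1..{self.max_ld}")

    def layer(self, n: int, mode: Mode = "exact") -> SimilarityLayer:
        self._check_layer(n)
        if mode == "exact":
            mask = self.edge_ld == n
        elif mode == "cumulative":
            mask = self.edge_ld <= n
        else:
            raise ValueError(f"unknown mode {mode!r}")
        edges = np.column_stack((self.edge_src[mask], self.edge_dst[mask]))
        return SimilarityLayer(n=n, mode=mode, edges=edges, n_nodes=self.n_nodes)


def cumulative_layer(net: LayeredNetwork, n: int) -> SimilarityLayer:
    """Union of exact layers 1..n (clones adjacent iff 1 <= LD <= n)."""
    return net.layer(n, mode="cumulative")


def layer_degrees(net: LayeredNetwork, n: int, mode: Mode = "exact") -> np.ndarray:
    """Degree vector of layer ``n`` computed from the sparse triangle
    directly (streaming path; no graph object is built)."""
    net._check_layer(n)
    if mode == "exact":
        mask = net.edge_ld == n
    elif mode == "cumulative":
        mask = net.edge_ld <= n
    else:
        raise ValueError(f"unknown mode {mode!r}")
    deg = np.zeros(net.n_nodes, dtype=np.int64)
    deg += np.bincount(net.edge_src[mask], minlength=net.n_nodes)
    deg += np.bincount(net.edge_dst[mask], minlength=net.n_nodes)
    return deg


def _row_chunks(n: int, chunk_size: int) -> Iterator[range]:
    for start in range(0, n, chunk_size):
        yield range(start, min(start + chunk_size, n))


def _chunk_pairs(
    seqs: Sequence[str], rows: range, max_ld: int
) -> tuple[list[int], list[int], list[int]]:
    """All pairs (i, j), i in rows, j > i, with LD <= max_ld.

    Length pruning: |len(a) - len(b)| > max_ld already implies LD > max_ld.
    """
    n = len(seqs)
    lens = [len(s) for s in seqs]
    ii: list[int] = []
    jj: list[int] = []
    dd: list[int] = []
    for i in rows:
        a, la = seqs[i], lens[i]
        for j in range(i + 1, n):
            if abs(la - lens[j]) > max_ld:
                continue
            d = _banded_distance(a, seqs[j], max_ld)
            if 1 <= d <= max_ld:
                ii.append(i)
                jj.append(j)
                dd.append(d)
    return ii, jj, dd


def compute_layers(
    rep: Repertoire,
    max_ld: int = 1,
    chunk_size: int = 512,
    workers: int = 1,
) -> LayeredNetwork:
    """Compute the sparse triangle of pairwise Levenshtein distances <= max_ld
    and wrap it as a :class:`LayeredNetwork`.

    The i < j triangle is partitioned into independent row chunks whose
    results are merged by union, so the edge set is identical for any
    ``chunk_size``/``workers`` configuration.
    """
    if not 1 <= max_ld <= MAX_SUPPORTED_LD:
        raise ValueError(f"max_ld must be in 1..{MAX_SUPPORTED_LD}, got {max_ld}")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    seqs = rep.sequences
    chunks = list(_row_chunks(len(seqs), chunk_size))
    if workers > 1 and len(chunks) > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(_chunk_pairs)(seqs, rows, max_ld) for rows in chunks
        )
    else:
        results = [_chunk_pairs(seqs, rows, max_ld) for rows in chunks]
    ii = [i for r in results for i in r[0]]
    jj = [j for r in results for j in r[1]]
    dd = [d for r in results for d in r[2]]
    return LayeredNetwork(
        sequences=list(seqs),
        max_ld=max_ld,
        edge_src=np.array(ii, dtype=np.int64),
        edge_dst=np.array(jj, dtype=np.int64),
        edge_ld=np.array(dd, dtype=np.int64),
        counts=rep.counts,
        v_genes=[c.v_gene for c in rep.clones],
        sample_id=rep.sample_id,
    )


def stream_layer_degree_counts(
    rep: Repertoire, max_ld: int, chunk_size: int = 512
) -> np.ndarray:
    """Degree-only path: per-clone degrees for every exact layer 1..max_ld
    without ever materializing the edge list.

    Returns an (n_clones, max_ld) matrix; column n-1 holds exact-layer-n
    degrees.  Chunk results are reduced by summation, mirroring a map-reduce
    degree count, and must equal :func:`layer_degrees` on the materialized
    network.
    """
    seqs = rep.sequences
    n = len(seqs)
    deg = np.zeros((n, max_ld), dtype=np.int64)
    for rows in _row_chunks(n, chunk_size):
        ii, jj, dd = _chunk_pairs(seqs, rows, max_ld)
        for i, j, d in zip(ii, jj, dd):
            deg[i, d - 1] += 1
            deg[j, d - 1] += 1
    return deg
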
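"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive and dense (plain numpy / pure python),
sharing no code path with the package: BFS reachability, explicit geodesic
counting, dense eigendecompositions, literal leave-one-out refits, and the
textbook dynamic-programming edit distance.
"""

from __future__ import annotations

import numpy as np


def dp_levenshtein(a: str, b: str) -> int:
    """Classic O(|a||b|) dynamic-programming edit distance."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[lb]


def adjacency_matrix(edges: np.ndarray, n: int) -> np.ndarray:
    a = np.zeros((n, n), dtype=float)
    for i, j in np.asarray(edges, dtype=int).reshape(-1, 2):
        a[i, j] = a[j, i] = 1.0
    return a


def bfs_distances(a: np.ndarray, source: int) -> np.ndarray:
    n = a.shape[0]
    dist = np.full(n, -1, dtype=int)
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(a[u]):
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(int(v))
        frontier = nxt
    return dist


def components(a: np.ndarray) -> list[list[int]]:
    n = a.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        dist = bfs_distances(a, s)
        members = np.flatnonzero(dist >= 0)
        seen[members] = True
        comps.append(members.tolist())
    return comps


def diameter_largest_component(a: np.ndarray) -> int | None:
    if a.sum() == 0:
        return None
    comp = max(components(a), key=len)
    best = 0
    for s in comp:
        d = bfs_distances(a, s)
        best = max(best, int(d[comp].max()))
    return best


def transitivity(a: np.ndarray) -> float:
    n = a.shape[0]
    triangles = triples = 0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                e = a[i, j] + a[j, k] + a[i, k]
                if e == 3:
                    triangles += 1
    deg = a.sum(axis=1)
    triples = float((deg * (deg - 1)).sum() / 2)
    return 3.0 * triangles / triples if triples > 0 else 0.0


def local_clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            a[x, y] for ii, x in enumerate(nbrs) for y in nbrs[ii + 1:]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def assortativity(a: np.ndarray) -> float | None:
    deg = a.sum(axis=1)
    xs, ys = [], []
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    if not xs:
        return None
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0 or ys.std() == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def centralization(a: np.ndarray) -> float | None:
    deg = a.sum(axis=1)
    n = a.shape[0]
    if n < 3:
        return None
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def eigenvector_centrality(a: np.ndarray) -> np.ndarray:
    if a.sum() == 0:
        return np.zeros(a.shape[0])
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    return vec / vec.max()


def authority(a: np.ndarray) -> np.ndarray:
    """Principal eigenvector of A^T A.  On an undirected graph this is the
    nonnegative dominant eigenvector of A itself (lambda_max^2 dominates
    A^T A, and |v_1| is the Perron resolution of the bipartite +/-lambda
    degeneracy), so the well-posed reference is computed from eigh(A)."""
    if a.sum() == 0:
        return np.zeros(a.shape[0])
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    return vec / vec.max()


def pagerank(a: np.ndarray, alpha: float = 0.85) -> np.ndarray:
    """Exact PageRank by dense linear solve; dangling nodes teleport
    uniformly (the standard convention)."""
    n = a.shape[0]
    deg = a.sum(axis=1)
    p = np.full((n, n), 1.0 / n)
    nz = deg > 0
    p[nz] = a[nz] / deg[nz, None]
    pi = np.linalg.solve(np.eye(n) - alpha * p.T, np.full(n, (1 - alpha) / n))
    return pi / pi.sum()


def _geodesic_counts(a: np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    """(distances, number of shortest paths) from s, by level DP."""
    n = a.shape[0]
    dist = bfs_distances(a, s)
    sigma = np.zeros(n)
    sigma[s] = 1
    order = np.argsort(np.where(dist < 0, np.inf, dist))
    for v in order:
        if dist[v] <= 0:
            continue
        preds = [u for u in np.flatnonzero(a[v]) if dist[u] == dist[v] - 1]
        sigma[v] = sum(sigma[u] for u in preds)
    return dist, sigma


def betweenness(a: np.ndarray) -> np.ndarray:
    """Unnormalized node betweenness by explicit geodesic counting over all
    unordered pairs."""
    n = a.shape[0]
    dist = np.array([bfs_distances(a, s) for s in range(n)])
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s] = _geodesic_counts(a, s)[1]
    b = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if dist[s, t] <= 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] >= 0 and dist[v, t] >= 0 and dist[s, v] + dist[v, t] == dist[s, t]:
                    b[v] += sigma[s, v] * sigma[t, v] / sigma[s, t]
    return b


def closeness(a: np.ndarray) -> np.ndarray:
    """Within-component closeness normalized by (component size - 1)."""
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        dist = bfs_distances(a, v)
        reach = np.flatnonzero(dist > 0)
        if reach.size == 0:
            continue
        # raw closeness 1/sum(d) times (component size - 1) == reach.size
        out[v] = reach.size / dist[reach].sum()
    return out


def _kcore_members(a: np.ndarray, k: int) -> np.ndarray:
    """Nodes surviving iterative removal of vertices with degree < k."""
    alive = np.ones(a.shape[0], dtype=bool)
    while True:
        deg = (a * alive).sum(axis=1)
        peel = alive & (deg < k)
        if not peel.any():
            return alive
        alive &= ~peel


def coreness(a: np.ndarray) -> np.ndarray:
    """Coreness per node: largest k whose k-core contains the node,
    found by re-running the shell peeling from scratch for every k."""
    n = a.shape[0]
    core = np.zeros(n, dtype=int)
    for k in range(1, n + 1):
        members = _kcore_members(a, k)
        if not members.any():
            break
        core[members] = k
    return core


def literal_loocv(x: np.ndarray, y: np.ndarray) -> tuple[float | None, float, float]:
    """Literal n-fold leave-one-out refit of y = b0 + b1 x."""
    n = len(x)
    press = 0.0
    for j in range(n):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        xj, yj = x[mask], y[mask]
        if np.ptp(xj) == 0:
            pred = yj.mean()
        else:
            b1, b0 = np.polyfit(xj, yj, 1)
            pred = b0 + b1 * x[j]
        press += (y[j] - pred) ** 2
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = None if tss == 0 else (1 - press / tss) * 100.0
    return q2, float(press), tss
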
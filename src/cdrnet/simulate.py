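"""Synthetic inputs: reference random graphs and synthetic CDR3 repertoires.

Graph generators provide the three reference topologies used to calibrate
the degree-distribution classifier: Erdős–Rényi (Poisson degrees),
Barabási–Albert preferential attachment (power-law degrees), and a
configuration model over a geometric degree sequence (exponential degrees).
A Bernoulli edge process cannot produce an exponential degree law, so the
exponential family is generated explicitly from its degree sequence.

Repertoire generators emulate the two similarity architectures seen along
B-cell development — tree-like (descendants chained off earlier descendants
by single substitutions, as VDJ recombination variants) and star-like (many
descendants radiating from few ancestors, as post-expansion mutants) — plus
cohorts with a controllable fraction of public clones shared across
individuals.  They emulate sequence-similarity topology and clone-count
skew, not immunogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .repertoire import CloneRecord, Repertoire

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_MODELS = ("erdos_renyi", "barabasi_albert", "exponential_config")


@dataclass
class SimulatedGraph:
    model: str
    n: int
    params: dict
    seed: int | None
    edges: np.ndarray  # (m, 2) int64, i < j

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def degrees(self) -> np.ndarray:
        from .distance import degrees_from_edges

        return degrees_from_edges(self.edges, self.n)

    def to_layer(self):
        from .distance import SimilarityLayer

        return SimilarityLayer(n=1, mode="exact", edges=self.edges, n_nodes=self.n)


def _edges_array(g: nx.Graph, n: int) -> np.ndarray:
    if g.number_of_edges() == 0:
        return np.empty((0, 2), dtype=np.int64)
    e = np.array([(min(u, v), max(u, v)) for u, v in g.edges() if u != v], dtype=np.int64)
    e = np.unique(e, axis=0)
    return e


def geometric_degree_sequence(
    n: int, mean_degree: float, rng: np.random.Generator
) -> np.ndarray:
    """Geometric degree sequence on {1, 2, ...} with the requested mean
    (discrete exponential law P(k) ~ q^k); the sum is forced even so a
    configuration model is realizable."""
    if mean_degree <= 1:
        raise ValueError("mean_degree must exceed 1 for a geometric law on k >= 1")
    p = 1.0 / mean_degree
    seq = rng.geometric(p, size=n)
    if seq.sum() % 2:
        seq[rng.integers(n)] += 1
    return seq.astype(np.int64)


def simulate_graph(
    model: str,
    n: int,
    params: dict | None = None,
    seed: int | None = None,
    max_retries: int = 20,
) -> SimulatedGraph:
    """Simulate a reference random graph.

    * ``erdos_renyi``: each pair independently with probability ``p``
      (or derived from ``mean_degree``).
    * ``barabasi_albert``: preferential attachment, ``m`` edges per new node.
    * ``exponential_config``: configuration model on a geometric degree
      sequence with ``mean_degree``; multi-edges/self-loops are simplified,
      and an infeasible sequence is resampled up to ``max_retries`` times.

    Seeded runs reproduce identical edge sets.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {_MODELS}")
    if n < 2:
        raise ValueError("n must be >= 2")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if model == "erdos_renyi":
        if "p" in params:
            p = float(params["p"])
        elif "mean_degree" in params:
            p = float(params["mean_degree"]) / (n - 1)
        else:
            raise ValueError("erdos_renyi requires 'p' or 'mean_degree'")
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        params = {"p": p}
    elif model == "barabasi_albert":
        m = int(params.get("m", 2))
        if not 1 <= m < n:
            raise ValueError("barabasi_albert requires 1 <= m < n")
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
        params = {"m": m}
    else:  # exponential_config
        mean_degree = float(params.get("mean_degree", 5.0))
        last_err: Exception | None = None
        for _ in range(max_retries):
            seq = geometric_degree_sequence(n, mean_degree, rng)
            try:
                g = nx.configuration_model(seq, seed=int(rng.integers(2**31)))
                break
            except nx.NetworkXError as err:  # pragma: no cover - rare
                last_err = err
        else:  # pragma: no cover
            raise RuntimeError(
                f"no realizable degree sequence after {max_retries} tries"
            ) from last_err
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
        params = {"mean_degree": mean_degree}
    return SimulatedGraph(model=model, n=n, params=params, seed=seed, edges=_edges_array(g, n))


def _random_sequence(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(AA, size=length))


def _substitute(seq: str, rng: np.random.Generator) -> str:
    """One random substitution (an LD-1 edit preserving length)."""
    pos = int(rng.integers(len(seq)))
    old = seq[pos]
    choices = AA[AA != old]
    return seq[:pos] + str(rng.choice(choices)) + seq[pos + 1:]


def _heavy_tailed_counts(
    rng: np.random.Generator, size: int, zipf_exponent: float = 2.5, cap: int = 10_000
) -> np.ndarray:
    """Clone counts: 1 + a capped Zipf draw, so every clone occurred more
    than once (survives the default repertoire filter) with a heavy tail."""
    return 1 + np.minimum(rng.zipf(zipf_exponent, size=size), cap)


def synthetic_repertoire(
    n_clones: int,
    length_range: tuple[int, int] = (4, 20),
    n_ancestors: int | None = None,
    mutations_per_descendant: int = 1,
    topology: str = "tree",
    seed: int | np.random.Generator | None = None,
    sample_id: str = "synthetic",
    zipf_exponent: float = 2.5,
    forbidden: set[str] | None = None,
    max_attempts_factor: int = 200,
) -> Repertoire:
    """Generate a repertoire of unique CDR3 strings with controllable LD_1
    topology.

    ``n_ancestors`` unrelated founder sequences are drawn uniformly over the
    20-letter alphabet (lengths uniform in ``length_range``); the remaining
    clones are descendants created by ``mutations_per_descendant`` single
    substitutions from a parent.  ``topology="tree"`` picks the parent among
    all existing clones (chain-like components); ``topology="star"`` picks
    only among ancestors (radial components).  With
    ``n_ancestors == n_clones`` there are no descendants at all and the LD_1
    layer is (with high probability) edgeless.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if topology not in ("tree", "star"):
        raise ValueError("topology must be 'tree' or 'star'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_ancestors is None:
        n_ancestors = max(1, n_clones // 10)
    n_ancestors = min(n_ancestors, n_clones)
    used: set[str] = set(forbidden or ())
    seqs: list[str] = []
    attempts_cap = max_attempts_factor * n_clones

    def admit(candidate: str) -> bool:
        if candidate in used:
            return False
        used.add(candidate)
        seqs.append(candidate)
        return True

    attempts = 0
    while len(seqs) < n_ancestors:
        attempts += 1
        if attempts > attempts_cap:
            raise RuntimeError("could not generate enough unique ancestor sequences")
        admit(_random_sequence(rng, length_range))
    while len(seqs) < n_clones:
        attempts += 1
        if attempts > attempts_cap:
            raise RuntimeError(
                "could not generate enough unique descendants; "
                "reduce n_clones or widen length_range"
            )
        pool = seqs[:n_ancestors] if topology == "star" else seqs
        parent = pool[int(rng.integers(len(pool)))]
        child = parent
        for _ in range(max(1, mutations_per_descendant)):
            child = _substitute(child, rng)
        admit(child)
    counts = _heavy_tailed_counts(rng, n_clones, zipf_exponent)
    clones = [CloneRecord(s, int(c)) for s, c in zip(seqs, counts)]
    return Repertoire(sample_id=sample_id, clones=clones)


@dataclass
class SyntheticCohort:
    repertoires: list[Repertoire]
    public_pool: frozenset[str]
    public_fraction: float
    seed: int | None
    ancestry: dict = field(default_factory=dict)


def synthetic_cohort(
    n_individuals: int,
    public_fraction: float,
    n_clones: int = 200,
    seed: int | None = None,
    public_as_hubs: bool = False,
    cohort: str = "synthetic-cohort",
    **repertoire_kwargs,
) -> SyntheticCohort:
    """Cohort of individuals sharing an injected public clone pool.

    The pool (``round(public_fraction * n_clones)`` sequences) is inserted
    into every individual, so each individual's realized public fraction
    equals the target exactly and public-clone detection recovers the pool.
    Private clones are unique across the whole cohort by construction.
    With ``public_as_hubs`` each individual's private clones are radial
    single-substitution neighbours of pool members, making public clones the
    LD_1 hubs of every repertoire.
    """
    if n_individuals < 2:
        raise ValueError("a cohort needs >= 2 individuals")
    if not 0 <= public_fraction < 1:
        raise ValueError("public_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    length_range = repertoire_kwargs.pop("length_range", (4, 20))
    n_public = int(round(public_fraction * n_clones))
    if n_public > n_clones:
        raise ValueError("public_fraction target exceeds repertoire size")
    used: set[str] = set()
    pool: list[str] = []
    while len(pool) < n_public:
        s = _random_sequence(rng, length_range)
        if s not in used:
            used.add(s)
            pool.append(s)
    reps: list[Repertoire] = []
    n_private = n_clones - n_public
    for i in range(n_individuals):
        if n_private:
            if public_as_hubs and pool:
                private: list[str] = []
                guard = 0
                while len(private) < n_private:
                    guard += 1
                    if guard > 200 * n_private:
                        raise RuntimeError("could not generate unique hub neighbours")
                    child = _substitute(pool[int(rng.integers(len(pool)))], rng)
                    if child not in used:
                        used.add(child)
                        private.append(child)
            else:
                private_rep = synthetic_repertoire(
                    n_private,
                    length_range=length_range,
                    seed=rng,
                    forbidden=used,
                    sample_id="tmp",
                    **repertoire_kwargs,
                )
                private = private_rep.sequences
                used.update(private)
        else:
            private = []
        seqs = pool + private
        counts = _heavy_tailed_counts(rng, len(seqs))
        clones = [CloneRecord(s, int(c)) for s, c in zip(seqs, counts)]
        reps.append(
            Repertoire(sample_id=f"ind{i + 1}", clones=clones, cohort=cohort)
        )
    return SyntheticCohort(
        repertoires=reps,
        public_pool=frozenset(pool),
        public_fraction=public_fraction,
        seed=seed,
    )
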
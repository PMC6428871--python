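"""Robustness experiments: clone removal and re-classification.

The architecture of a repertoire is probed by deleting clones — either the
*public* clones shared across individuals of a cohort, or uniformly random
clone subsets of matched size — and re-classifying the degree distribution
of the surviving similarity network.  Removal uses subgraph induction (all
edges among surviving clones are kept), which is identical to recomputing
Levenshtein layers on the surviving clones since pairwise distances do not
depend on the rest of the repertoire.

A classification that is infeasible after removal (too little tail left to
fit) is recorded as ``None`` — the "NA" outcome — rather than raised.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .degree_fit import (
    DegreeDistributionFit,
    InfeasibleFitError,
    classify_distribution,
)
from .distance import LayeredNetwork, SimilarityLayer, degrees_from_edges
from .graph_metrics import connected_components
from .repertoire import PublicCloneSet, Repertoire


@dataclass(frozen=True)
class MetricsDelta:
    """Change in the cheap global metrics caused by one removal
    (removal can only decrease each of them)."""

    n_nodes: int
    n_edges: int
    largest_component_size: int
    d_nodes: int
    d_edges: int
    d_largest_component: int


@dataclass
class RemovalOutcome:
    """One removal replicate: surviving-network classification + deltas."""

    fit: DegreeDistributionFit | None     # None == NA (fit not feasible)
    delta: MetricsDelta

    @property
    def family(self) -> str | None:
        return self.fit.family if self.fit is not None else None


@dataclass
class RemovalExperiment:
    strategy: str                          # "public" | "random"
    fraction: float | None                 # None for size-of-public removal
    reps: int
    seed: int | None
    sample_id: str
    baseline: DegreeDistributionFit | None
    outcomes: list[RemovalOutcome] = field(default_factory=list)

    def families(self) -> list[str | None]:
        return [o.family for o in self.outcomes]

    def modal_family(self) -> str | None:
        """Most frequent classification over replicates (NA counts too)."""
        if not self.outcomes:
            return None
        return Counter(self.families()).most_common(1)[0][0]


def surviving_edges(edges: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Edges of the induced subgraph on the kept nodes (original indices)."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.size == 0:
        return edges
    mask = keep[edges[:, 0]] & keep[edges[:, 1]]
    return edges[mask]


def _removal_outcome(
    edges: np.ndarray,
    n_nodes: int,
    keep: np.ndarray,
    baseline_largest: int,
    n_boot: int,
    rng: np.random.Generator,
    classify_kwargs: dict,
) -> RemovalOutcome:
    kept_idx = np.flatnonzero(keep)
    sub_edges = surviving_edges(edges, keep)
    deg = degrees_from_edges(sub_edges, n_nodes)[kept_idx]
    layer = SimilarityLayer(n=1, mode="exact", edges=sub_edges, n_nodes=n_nodes)
    comps = connected_components(layer)
    # components among kept nodes only (removed nodes are isolated singletons)
    if kept_idx.size:
        kept_labels = comps.labels[kept_idx]
        largest = int(np.bincount(kept_labels).max())
    else:
        largest = 0
    delta = MetricsDelta(
        n_nodes=int(kept_idx.size),
        n_edges=int(sub_edges.shape[0]),
        largest_component_size=largest,
        d_nodes=n_nodes - int(kept_idx.size),
        d_edges=int(np.asarray(edges).reshape(-1, 2).shape[0] - sub_edges.shape[0]),
        d_largest_component=baseline_largest - largest,
    )
    try:
        fit = classify_distribution(deg, n_boot=n_boot, seed=rng, **classify_kwargs)
    except InfeasibleFitError:
        fit = None
    return RemovalOutcome(fit=fit, delta=delta)


def random_removal_experiment_edges(
    edges: np.ndarray,
    n_nodes: int,
    fraction: float,
    reps: int = 20,
    seed: int | np.random.Generator | None = None,
    n_boot: int = 100,
    baseline: DegreeDistributionFit | None = None,
    sample_id: str = "",
    **classify_kwargs,
) -> RemovalExperiment:
    """Random-removal experiment on a raw edge set (graph-level core).

    Per replicate, ``fraction`` of the nodes is removed uniformly without
    replacement, the induced subgraph degrees are recomputed and the degree
    distribution is re-classified.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_remove = int(round(fraction * n_nodes))
    if n_remove >= n_nodes:
        raise ValueError("fraction would remove every clone")
    if baseline is None:
        deg0 = degrees_from_edges(edges, n_nodes)
        try:
            baseline = classify_distribution(
                deg0, n_boot=n_boot, seed=rng, **classify_kwargs
            )
        except InfeasibleFitError:
            baseline = None
    layer0 = SimilarityLayer(n=1, mode="exact", edges=np.asarray(edges), n_nodes=n_nodes)
    baseline_largest = connected_components(layer0).largest_size
    exp = RemovalExperiment(
        strategy="random",
        fraction=fraction,
        reps=reps,
        seed=None if isinstance(seed, np.random.Generator) else seed,
        sample_id=sample_id,
        baseline=baseline,
    )
    for _ in range(reps):
        keep = np.ones(n_nodes, dtype=bool)
        keep[rng.choice(n_nodes, size=n_remove, replace=False)] = False
        exp.outcomes.append(
            _removal_outcome(
                edges, n_nodes, keep, baseline_largest, n_boot, rng, classify_kwargs
            )
        )
    return exp


def remove_random_experiment(
    rep: Repertoire,
    net: LayeredNetwork,
    fraction: float,
    reps: int = 20,
    seed: int | np.random.Generator | None = None,
    n_boot: int = 100,
    layer: int = 1,
    mode: str = "exact",
    **classify_kwargs,
) -> RemovalExperiment:
    """Random removal of a clone fraction from a repertoire network."""
    lay = net.layer(layer, mode)
    return random_removal_experiment_edges(
        lay.edges,
        net.n_nodes,
        fraction,
        reps=reps,
        seed=seed,
        n_boot=n_boot,
        sample_id=rep.sample_id,
        **classify_kwargs,
    )


def random_removal_robustness(
    edges: np.ndarray,
    n_nodes: int,
    fractions: tuple[float, ...] = (0.1, 0.5, 0.9),
    reps: int = 20,
    seed: int | None = None,
    n_boot: int = 100,
    **classify_kwargs,
) -> dict:
    """Removal grid summary: the robustness verdict is the largest tested
    fraction at which the modal classification over replicates equals the
    unperturbed network's classification.
    """
    rng = np.random.default_rng(seed)
    deg0 = degrees_from_edges(edges, n_nodes)
    baseline = classify_distribution(deg0, n_boot=n_boot, seed=rng, **classify_kwargs)
    experiments = {}
    for f in sorted(fractions):
        experiments[f] = random_removal_experiment_edges(
            edges, n_nodes, f, reps=reps, seed=rng, n_boot=n_boot,
            baseline=baseline, **classify_kwargs,
        )
    robust = [f for f, e in experiments.items() if e.modal_family() == baseline.family]
    return {
        "baseline": baseline,
        "experiments": experiments,
        "max_robust_fraction": max(robust) if robust else 0.0,
    }


def remove_public_experiment(
    reps: list[Repertoire],
    nets: list[LayeredNetwork],
    public: PublicCloneSet,
    control_reps: int = 20,
    seed: int | np.random.Generator | None = None,
    n_boot: int = 100,
    layer: int = 1,
    mode: str = "exact",
    **classify_kwargs,
) -> list[dict]:
    """Remove exactly the public clones from each sample and re-classify;
    also runs the matched random control (removal of the same clone count,
    ``control_reps`` times).

    Returns one record per sample: the public-removal experiment (a single
    deterministic outcome) and its matched random control.
    """
    if len(reps) != len(nets):
        raise ValueError("repertoires and networks must be paired")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results = []
    for rep, net in zip(reps, nets):
        lay = net.layer(layer, mode)
        n = net.n_nodes
        is_public = np.array([s in public for s in net.sequences], dtype=bool)
        n_pub = int(is_public.sum())
        if n_pub == 0:
            import warnings

            warnings.warn(
                f"{rep.sample_id}: no public clones present; removal is a no-op",
                stacklevel=2,
            )
        deg0 = degrees_from_edges(lay.edges, n)
        try:
            baseline = classify_distribution(
                deg0, n_boot=n_boot, seed=rng, **classify_kwargs
            )
        except InfeasibleFitError:
            baseline = None
        baseline_largest = connected_components(lay).largest_size
        pub_exp = RemovalExperiment(
            strategy="public", fraction=None, reps=1,
            seed=None, sample_id=rep.sample_id, baseline=baseline,
        )
        pub_exp.outcomes.append(
            _removal_outcome(
                lay.edges, n, ~is_public, baseline_largest, n_boot, rng,
                classify_kwargs,
            )
        )
        control = RemovalExperiment(
            strategy="random", fraction=None, reps=control_reps,
            seed=None, sample_id=rep.sample_id, baseline=baseline,
        )
        if n_pub:
            for _ in range(control_reps):
                keep = np.ones(n, dtype=bool)
                keep[rng.choice(n, size=n_pub, replace=False)] = False
                control.outcomes.append(
                    _removal_outcome(
                        lay.edges, n, keep, baseline_largest, n_boot, rng,
                        classify_kwargs,
                    )
                )
        results.append(
            {
                "sample_id": rep.sample_id,
                "n_public_removed": n_pub,
                "public": pub_exp,
                "matched_random": control,
            }
        )
    return results


def public_connectivity(
    rep: Repertoire,
    net: LayeredNetwork,
    public: PublicCloneSet,
    layer: int = 1,
    mode: str = "exact",
) -> tuple[float, np.ndarray]:
    """Fraction of private clones adjacent to at least one public clone in
    the given layer, plus the per-clone public flag vector (for rank
    overlays against authority or frequency)."""
    lay = net.layer(layer, mode)
    is_public = np.array([s in public for s in net.sequences], dtype=bool)
    n_private = int((~is_public).sum())
    if n_private == 0:
        return 0.0, is_public
    touched = np.zeros(net.n_nodes, dtype=bool)
    e = lay.edges
    if e.size:
        touched[e[:, 0]] |= is_public[e[:, 1]]
        touched[e[:, 1]] |= is_public[e[:, 0]]
    frac = float((touched & ~is_public).sum() / n_private)
    return frac, is_public
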
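import numpy as np
import pytest

from cdrnet.distance import compute_layers, degrees_from_edges
from cdrnet.perturbation import (
    public_connectivity,
    random_removal_experiment_edges,
    remove_public_experiment,
    remove_random_experiment,
    surviving_edges,
)
from cdrnet.repertoire import CloneRecord, Repertoire, find_public_clones
from cdrnet.simulate import simulate_graph, synthetic_cohort, synthetic_repertoire


def _rep(seqs, sid="t"):
    return Repertoire(sid, [CloneRecord(s, 2) for s in seqs])


class TestSubgraphInduction:
    def test_equals_ld_recomputation(self):
        """Keeping edges among survivors == recomputing LD on survivors."""
        rep = synthetic_repertoire(50, seed=1, n_ancestors=5)
        net = compute_layers(rep, max_ld=1)
        rng = np.random.default_rng(0)
        keep = rng.random(50) > 0.4
        sub = surviving_edges(net.layer(1).edges, keep)
        kept_idx = np.flatnonzero(keep)
        deg_induced = degrees_from_edges(sub, 50)[kept_idx]
        survivors = _rep([rep.sequences[i] for i in kept_idx])
        renet = compute_layers(survivors, max_ld=1)
        assert np.array_equal(deg_induced, renet.layer(1).degrees())

    def test_removal_never_increases_counts(self):
        g = simulate_graph("erdos_renyi", 400, {"mean_degree": 4}, seed=2)
        exp = random_removal_experiment_edges(
            g.edges, g.n, 0.3, reps=5, seed=3, n_boot=5
        )
        for o in exp.outcomes:
            assert o.delta.d_nodes >= 0
            assert o.delta.d_edges >= 0
            assert o.delta.d_largest_component >= 0

    def test_expected_edge_survival(self):
        """At removal fraction f, ~(1-f)^2 of an ER graph's edges survive."""
        g = simulate_graph("erdos_renyi", 2000, {"mean_degree": 6}, seed=4)
        exp = random_removal_experiment_edges(
            g.edges, g.n, 0.5, reps=10, seed=5, n_boot=2
        )
        survived = np.mean([o.delta.n_edges for o in exp.outcomes])
        expected = 0.25 * g.n_edges
        sd = np.sqrt(g.n_edges * 0.25 * 0.75)
        assert abs(survived - expected) < 4 * sd


class TestRandomRemoval:
    def test_seeded_runs_reproducible(self):
        g = simulate_graph("exponential_config", 800, {"mean_degree": 4}, seed=6)
        e1 = random_removal_experiment_edges(g.edges, g.n, 0.2, reps=3, seed=11, n_boot=10)
        e2 = random_removal_experiment_edges(g.edges, g.n, 0.2, reps=3, seed=11, n_boot=10)
        assert e1.families() == e2.families()
        assert [o.delta.n_edges for o in e1.outcomes] == [
            o.delta.n_edges for o in e2.outcomes
        ]

    def test_tiny_network_90pct_removal_records_na(self):
        rep = synthetic_repertoire(10, seed=3, n_ancestors=1, topology="star")
        net = compute_layers(rep, max_ld=1)
        exp = remove_random_experiment(rep, net, 0.9, reps=3, seed=0, n_boot=5)
        assert all(o.fit is None for o in exp.outcomes)
        assert exp.modal_family() is None  # the NA outcome

    def test_fraction_bounds(self):
        g = simulate_graph("erdos_renyi", 50, {"mean_degree": 3}, seed=0)
        with pytest.raises(ValueError):
            random_removal_experiment_edges(g.edges, g.n, 1.0, reps=1, seed=0)


class TestPublicRemoval:
    def test_no_shared_clones_is_noop(self):
        cohort = synthetic_cohort(3, 0.0, n_clones=40, seed=9)
        reps = cohort.repertoires
        pub = find_public_clones(reps)
        nets = [compute_layers(r, max_ld=1) for r in reps]
        with pytest.warns(UserWarning, match="no public clones"):
            results = remove_public_experiment(reps, nets, pub, control_reps=2,
                                               seed=1, n_boot=5)
        for res, net in zip(results, nets):
            assert res["n_public_removed"] == 0
            assert res["public"].outcomes[0].delta.n_nodes == net.n_nodes

    def test_hub_public_removal_shrinks_component_more_than_random(self):
        cohort = synthetic_cohort(3, 0.15, n_clones=120, seed=12,
                                  public_as_hubs=True)
        reps = cohort.repertoires
        pub = find_public_clones(reps)
        assert set(pub.clones) == set(cohort.public_pool)
        nets = [compute_layers(r, max_ld=1) for r in reps]
        results = remove_public_experiment(reps, nets, pub, control_reps=10,
                                           seed=2, n_boot=2)
        for res in results:
            pub_drop = res["public"].outcomes[0].delta.d_largest_component
            rand_drop = np.mean(
                [o.delta.d_largest_component for o in res["matched_random"].outcomes]
            )
            assert pub_drop > rand_drop

    def test_all_clones_public_empty_network(self):
        seqs = ["CARDY", "CARDW", "CAVVW"]
        reps = [_rep(seqs, "a"), _rep(seqs, "b")]
        pub = find_public_clones(reps)
        nets = [compute_layers(r, max_ld=1) for r in reps]
        results = remove_public_experiment(reps, nets, pub, control_reps=1,
                                           seed=0, n_boot=5)
        out = results[0]["public"].outcomes[0]
        assert out.delta.n_nodes == 0
        assert out.fit is None  # explicit NA


class TestPublicConnectivity:
    def test_empty_public_set_zero(self):
        reps = [_rep(["CARDY", "CARDW"], "a"), _rep(["CAAAA", "CAAAW"], "b")]
        pub = find_public_clones(reps)
        net = compute_layers(reps[0], max_ld=1)
        frac, flags = public_connectivity(reps[0], net, pub)
        assert frac == 0.0 and not flags.any()

    def test_star_public_hub_fraction_one(self):
        hub = "CARDY"
        leaves = ["AARDY", "CVRDY", "CARDD"]
        rep_a = _rep([hub] + leaves, "a")
        rep_b = _rep([hub, "WWWWW"], "b")
        pub = find_public_clones([rep_a, rep_b])
        net = compute_layers(rep_a, max_ld=1)
        frac, _ = public_connectivity(rep_a, net, pub)
        assert frac == 1.0

    def test_half_adjacent(self):
        # public CARDY adjacent to CARDW but not CAWWW
        rep_a = _rep(["CARDY", "CARDW", "CAWWW"], "a")
        rep_b = _rep(["CARDY"], "b")
        pub = find_public_clones([rep_a, rep_b])
        net = compute_layers(rep_a, max_ld=1)
        frac, _ = public_connectivity(rep_a, net, pub)
        assert frac == pytest.approx(0.5)
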
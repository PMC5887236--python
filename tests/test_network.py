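import networkx as nx
import numpy as np
import pytest

from conftest import atoms_of, matrix_from_bonds
from oracles import brute_force_paths_through
from reactnet import (
    CDCache,
    NetworkConfig,
    ReactionPath,
    SpeciesState,
    build_network,
    edge_frequency_ranking,
    extract_minimal_subnetwork,
    kinetic_filter,
    path_percentile,
    rank_paths_topq,
    remove_edge_and_paths,
    sample_paths,
    shortest_paths_through,
)
from reactnet.acmatrix import CanonicalKeyer


def halogen_network(halogen):
    atoms = halogen.atom_list()
    keyer = CanonicalKeyer(atoms)
    mats = halogen.mechanism_matrices()  # R, intermediate, P
    extra = matrix_from_bonds(6, [(0, 2), (1, 5), (4, 5)])  # I2? no: II + HCl + H?
    states = [SpeciesState(m, atoms, keyer.key(m), i) for i, m in enumerate(mats)]
    cache = CDCache(atoms)
    g = build_network(states, states[0].key, states[-1].key, cache)
    return g, states, cache


class TestBuild:
    def test_halogen_network_edges_and_weights(self, halogen):
        g, states, cache = halogen_network(halogen)
        r, mid, p = (s.key for s in states)
        assert g.has_edge(r, mid) and g.has_edge(mid, p)
        assert g.edges[r, mid]["weight"] == 4
        assert g.edges[mid, p]["weight"] == 4
        # direct R-P step would need 3 formations and 3 dissociations
        assert not g.has_edge(r, p)

    def test_caps_prevent_large_steps(self, halogen):
        atoms = halogen.atom_list()
        keyer = CanonicalKeyer(atoms)
        r = halogen.reactant_matrix()
        p = halogen.product_matrix()
        states = [SpeciesState(m, atoms, keyer.key(m), 0) for m in (r, p)]
        cache = CDCache(atoms)
        g = build_network(states, states[0].key, states[1].key, cache)
        assert g.number_of_edges() == 0
        relaxed = build_network(
            states, states[0].key, states[1].key, cache, NetworkConfig(max_form=3, max_break=3)
        )
        assert relaxed.number_of_edges() == 0  # still trimolecular
        relaxed2 = build_network(
            states,
            states[0].key,
            states[1].key,
            cache,
            NetworkConfig(max_form=3, max_break=3, molecularity=2),
        )
        # three molecules change bonds in both directions: stays absent
        assert relaxed2.number_of_edges() == 0

    def test_missing_endpoint_raises(self, halogen):
        atoms = halogen.atom_list()
        keyer = CanonicalKeyer(atoms)
        r = halogen.reactant_matrix()
        states = [SpeciesState(r, atoms, keyer.key(r), 0)]
        with pytest.raises(ValueError, match="vertices"):
            build_network(states, states[0].key, CanonicalKeyer(atoms).key(halogen.product_matrix()), CDCache(atoms))

    def test_catalyst_rule_drops_uninvolved_edges(self):
        symbols = ["Co", "H", "H", "Cl", "Cl"]
        atoms = atoms_of(symbols, catalyst=[0])
        keyer = CanonicalKeyer(atoms)
        r = matrix_from_bonds(5, [(0, 1), (2, 3)])  # Co-H + H-Cl
        b = matrix_from_bonds(5, [(0, 1), (3, 4)])  # H-Cl -> Cl-Cl, no Co involvement
        c = matrix_from_bonds(5, [(0, 1), (0, 2)])  # second H migrates onto Co
        states = [SpeciesState(m, atoms, keyer.key(m), 0) for m in (r, b, c)]
        cache = CDCache(atoms)
        g = build_network(states, states[0].key, states[2].key, cache)
        assert not g.has_edge(states[0].key, states[1].key)
        assert g.has_edge(states[0].key, states[2].key)
        free = build_network(
            states, states[0].key, states[2].key, cache, NetworkConfig(require_catalyst=False)
        )
        assert free.has_edge(states[0].key, states[1].key)


def toy_graph(edges, r="R", p="P"):
    g = nx.Graph(reactant=r, product=p)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


class TestPaths:
    def test_unique_geodesic_chain(self):
        g = toy_graph([("R", "v", 1), ("v", "P", 1)])
        paths = shortest_paths_through(g, "v")
        assert [p.keys for p in paths] == [("R", "v", "P")]
        assert paths[0].length == 2

    def test_diamond_ties_enumerated(self):
        g = toy_graph([("R", "a", 1), ("R", "b", 1), ("a", "v", 1), ("b", "v", 1), ("v", "P", 1)])
        paths = shortest_paths_through(g, "v")
        assert {p.keys for p in paths} == {("R", "a", "v", "P"), ("R", "b", "v", "P")}

    def test_disconnected_vertex_gives_empty(self):
        g = toy_graph([("R", "P", 1)])
        g.add_node("lonely")
        assert shortest_paths_through(g, "lonely") == []

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(5, 13))
            g = nx.Graph(reactant=0, product=n - 1)
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        g.add_edge(i, j, weight=int(rng.integers(1, 5)))
            if not nx.has_path(g, 0, n - 1):
                continue
            for v in g.nodes:
                got = {p.keys for p in shortest_paths_through(g, v)}
                want = set(brute_force_paths_through(g, 0, n - 1, v))
                assert got == want, (trial, v)

    def test_sampled_paths_are_loopless_with_correct_lengths(self):
        rng = np.random.default_rng(3)
        g = nx.Graph(reactant=0, product=7)
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.5:
                    g.add_edge(i, j, weight=int(rng.integers(1, 4)))
        assert nx.has_path(g, 0, 7)
        for path in sample_paths(g):
            assert path.keys[0] == 0 and path.keys[-1] == 7
            assert len(set(path.keys)) == len(path.keys)
            assert path.length == sum(
                g.edges[a, b]["weight"] for a, b in zip(path.keys, path.keys[1:])
            )

    def test_k_extension_adds_longer_paths(self):
        g = toy_graph([("R", "v", 1), ("v", "P", 1), ("R", "a", 1), ("a", "v", 2)])
        k1 = shortest_paths_through(g, "v", k=1)
        k2 = shortest_paths_through(g, "v", k=2)
        assert {p.keys for p in k1} < {p.keys for p in k2}
        assert ("R", "a", "v", "P") in {p.keys for p in k2}


class TestMinimalSubnetwork:
    def test_star_graph_keeps_only_spoke_chain(self):
        g = toy_graph(
            [("R", "x", 1), ("x", "P", 1), ("R", "y", 5), ("y", "z", 1)]
        )
        paths = sample_paths(g)
        sub = extract_minimal_subnetwork(g, paths)
        assert set(sub.nodes) == {"R", "x", "P"}
        assert sub.number_of_edges() == 2

    def test_every_edge_lies_on_a_sampled_path(self):
        rng = np.random.default_rng(11)
        g = nx.Graph(reactant=0, product=5)
        for i in range(6):
            for j in range(i + 1, 6):
                if rng.random() < 0.6:
                    g.add_edge(i, j, weight=int(rng.integers(1, 4)))
        assert nx.has_path(g, 0, 5)
        paths = sample_paths(g)
        sub = extract_minimal_subnetwork(g, paths)
        on_paths = set()
        for p in paths:
            for a, b in zip(p.keys, p.keys[1:]):
                on_paths.add(frozenset((a, b)))
        for a, b in sub.edges:
            assert frozenset((a, b)) in on_paths
        assert set(sub.edges) <= set(g.edges) | {(b, a) for a, b in g.edges}

    def test_disconnected_path_set_raises(self):
        g = toy_graph([("R", "x", 1), ("x", "P", 1)])
        bogus = [ReactionPath(("R", "x"), 1)]  # never reaches P
        with pytest.raises(ValueError, match="disconnected"):
            extract_minimal_subnetwork(g, bogus)


class TestRanking:
    def _paths(self, lengths):
        return [
            ReactionPath((f"R{i}", f"P{i}"), L) for i, L in enumerate(lengths)
        ]

    def test_q_one_keeps_all(self):
        paths = self._paths([6, 8, 10])
        assert len(rank_paths_topq(paths, 1.0)) == 3

    def test_tie_at_cutoff_kept(self):
        paths = self._paths([6, 6, 8, 10])
        kept = rank_paths_topq(paths, 0.5)
        assert [p.length for p in kept] == [6, 6]

    def test_ranks_and_percentiles(self):
        paths = self._paths([4, 6, 6, 8])
        kept = rank_paths_topq(paths, 1.0)
        assert [p.rank for p in kept] == [1, 2, 3, 4]
        assert kept[0].percentile == pytest.approx(25.0)
        assert kept[1].percentile == kept[2].percentile == pytest.approx(75.0)

    def test_stability_adding_longer_path(self):
        short = self._paths([4, 6])
        longer = short + self._paths([12])
        kept_a = rank_paths_topq(short, 1.0)
        kept_b = rank_paths_topq(longer, 1.0)
        assert [p.keys for p in kept_a] == [p.keys for p in kept_b[:2]]

    def test_empty_and_invalid_q(self):
        assert rank_paths_topq([], 0.5) == []
        with pytest.raises(ValueError):
            rank_paths_topq(self._paths([1]), 0.0)

    def test_path_percentile_lookup(self):
        paths = self._paths([4, 6, 8])
        assert path_percentile(paths, ("R1", "P1")) == pytest.approx(200 / 3)
        assert path_percentile(paths, ("nope",)) is None


class TestEdgeFrequency:
    def test_single_path_counts_once(self):
        g = toy_graph([("R", "v", 1), ("v", "P", 2)])
        paths = [ReactionPath(("R", "v", "P"), 3)]
        ranking = edge_frequency_ranking(paths, g)
        assert [count for _, count in ranking] == [1, 1]
        # tie broken by ascending weight
        assert ranking[0][0] == ("R", "v")

    def test_shared_edge_ranks_first(self):
        g = toy_graph([("R", "a", 1), ("R", "b", 1), ("a", "P", 1), ("b", "P", 1)])
        paths = [
            ReactionPath(("R", "a", "P"), 2),
            ReactionPath(("R", "a", "P"), 2),
            ReactionPath(("R", "b", "P"), 2),
        ]
        ranking = edge_frequency_ranking(paths, g)
        top_edge, top_count = ranking[0]
        assert top_count == 2 and set(top_edge) in ({"R", "a"}, {"a", "P"})
        total = sum(c for _, c in ranking)
        assert total == sum(len(p.keys) - 1 for p in paths)


def energy_graph(energies, edges, r="R", p="P"):
    atoms = atoms_of(["H", "H"])
    keyer = CanonicalKeyer(atoms)
    g = nx.Graph(reactant=r, product=p)
    a = matrix_from_bonds(2, [(0, 1)])
    for node, e in energies.items():
        s = SpeciesState(a, atoms, keyer.key(a), 0, energy=e)
        g.add_node(node, state=s)
    for x, y, w in edges:
        g.add_edge(x, y, weight=w)
    return g


class TestKineticFilter:
    def test_infinite_thresholds_keep_everything(self):
        g = energy_graph({"R": 0, "v": 30, "P": -5}, [("R", "v", 1), ("v", "P", 1)])
        out = kinetic_filter(g, float("inf"), float("inf"))
        assert set(out.nodes) == {"R", "v", "P"}

    def test_high_energy_pendant_vertex_removed(self):
        g = energy_graph(
            {"R": 0, "v": 50, "P": -5, "w": 5},
            [("R", "w", 1), ("w", "P", 1), ("R", "v", 1)],
        )
        out = kinetic_filter(g, 20.0, float("inf"))
        assert "v" not in out.nodes and "w" in out.nodes

    def test_uphill_edge_removed_and_pendant_dropped(self):
        g = energy_graph(
            {"R": 0, "a": 5, "b": 30, "P": 0},
            [("R", "a", 1), ("a", "b", 1), ("R", "P", 1)],
        )
        out = kinetic_filter(g, float("inf"), 20.0)
        assert not out.has_edge("a", "b")
        assert "b" not in out.nodes  # isolated after the edge drop
        assert "a" not in out.nodes or out.degree("a") > 0

    def test_r_and_p_always_retained(self):
        g = energy_graph({"R": 0, "P": 100}, [("R", "P", 1)])
        out = kinetic_filter(g, 20.0, 20.0)
        assert "R" in out.nodes and "P" in out.nodes

    def test_monotone_in_thresholds(self):
        g = energy_graph(
            {"R": 0, "a": 15, "b": 25, "P": 5},
            [("R", "a", 1), ("a", "b", 1), ("b", "P", 1), ("R", "b", 2)],
        )
        prev_nodes, prev_edges = set(), set()
        for tol in (0.0, 10.0, 30.0, 1e9):
            out = kinetic_filter(g, tol, tol)
            nodes = set(out.nodes)
            edges = {frozenset(e) for e in out.edges}
            assert prev_nodes <= nodes and prev_edges <= edges
            prev_nodes, prev_edges = nodes, edges

    def test_missing_energy_raises(self):
        g = energy_graph({"R": 0, "P": 0}, [("R", "P", 1)])
        g.nodes["P"]["state"].energy = None
        with pytest.raises(ValueError, match="energy"):
            kinetic_filter(g, 1.0, 1.0)


class TestRemoveEdge:
    def test_edge_on_no_path_leaves_paths(self):
        g = toy_graph([("R", "v", 1), ("v", "P", 1), ("R", "x", 1)])
        paths = [ReactionPath(("R", "v", "P"), 2)]
        g2, kept = remove_edge_and_paths(g, paths, ("R", "x"))
        assert kept == paths and not g2.has_edge("R", "x")

    def test_edge_on_every_path_empties(self):
        g = toy_graph([("R", "v", 1), ("v", "P", 1)])
        paths = [ReactionPath(("R", "v", "P"), 2)]
        g2, kept = remove_edge_and_paths(g, paths, ("v", "P"))
        assert kept == []

    def test_matches_membership_oracle_on_random_paths(self):
        rng = np.random.default_rng(5)
        g = nx.Graph(reactant=0, product=6)
        for i in range(7):
            for j in range(i + 1, 7):
                if rng.random() < 0.5:
                    g.add_edge(i, j, weight=1)
        if not nx.has_path(g, 0, 6):
            pytest.skip("random graph disconnected")
        paths = sample_paths(g)
        edge = sorted(g.edges)[0]
        _, kept = remove_edge_and_paths(g, paths, edge)
        want = [
            p
            for p in paths
            if all({a, b} != set(edge) for a, b in zip(p.keys, p.keys[1:]))
        ]
        assert kept == want

    def test_missing_edge_raises(self):
        g = toy_graph([("R", "P", 1)])
        with pytest.raises(ValueError):
            remove_edge_and_paths(g, [], ("R", "x"))
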
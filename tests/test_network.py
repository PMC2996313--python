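"""Kinetic-graph analytics: weights, betweenness, backbone, hub, KL."""

import heapq
import itertools

import networkx as nx
import numpy as np
import pytest

from rexmap import network


def brute_force_betweenness(G):
    """Independent oracle: Dijkstra + explicit shortest-path enumeration."""
    nodes = sorted(G.nodes)
    node_score = {v: 0.0 for v in nodes}
    edge_score = {tuple(sorted(e)): 0.0 for e in G.edges}

    def all_shortest_paths(s, t):
        # enumerate every simple path, keep the minimal-weight set
        best, paths = np.inf, []
        for path in nx.all_simple_paths(G, s, t):
            w = sum(G[a][b]["weight"] for a, b in zip(path, path[1:]))
            if w < best - 1e-12:
                best, paths = w, [path]
            elif abs(w - best) <= 1e-12:
                paths.append(path)
        return paths

    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                node_score[v] += 1.0 / len(paths)
            for a, b in zip(p, p[1:]):
                edge_score[tuple(sorted((a, b)))] += 1.0 / len(paths)
    return node_score, edge_score


def random_graph(rng, n=8):
    while True:
        G = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1 << 30)))
        if nx.is_connected(G):
            break
    for u, v in G.edges:
        G[u][v]["weight"] = float(rng.uniform(0.2, 2.0))
    return G


class TestEnergyGraph:
    def test_weight_is_minus_log_prob(self):
        T = np.array([[0.0, 1.0], [np.exp(-2), 1 - np.exp(-2)]])
        G = network.energy_graph(T, mode="directed")
        assert G[0][1]["weight"] == pytest.approx(0.0)
        assert G[1][0]["weight"] == pytest.approx(2.0)

    def test_zero_probability_pairs_have_no_edge(self):
        T = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        G = network.energy_graph(T, mode="directed")
        assert not G.has_edge(0, 2)
        assert not G.has_edge(0, 0)  # no self loops

    def test_shortest_path_is_most_probable_path(self, rng):
        """Path-enumeration oracle: min sum(-ln T) == max product(T)."""
        for _ in range(5):
            T = rng.dirichlet(np.ones(5), size=5)
            G = network.energy_graph(T, mode="directed")
            sp = nx.shortest_path(G, 0, 4, weight="weight")
            best_prob, best_path = -1.0, None
            for k in range(5):
                for mid in itertools.permutations([1, 2, 3], k):
                    path = (0,) + mid + (4,)
                    prob = np.prod([T[a, b] for a, b in zip(path, path[1:])])
                    if prob > best_prob:
                        best_prob, best_path = prob, path
            got = np.prod([T[a, b] for a, b in zip(sp, sp[1:])])
            assert got == pytest.approx(best_prob, rel=1e-9)


class TestBetweenness:
    def test_path_graph_analytic(self):
        G = nx.path_graph(3)
        nx.set_edge_attributes(G, 1.0, "weight")
        sc = network.betweenness(G)
        assert sc.node[1] == 1.0 and sc.node[0] == 0.0 and sc.node[2] == 0.0

    def test_complete_graph_all_zero(self):
        G = nx.complete_graph(5)
        nx.set_edge_attributes(G, 1.0, "weight")
        sc = network.betweenness(G)
        assert all(v == 0.0 for v in sc.node.values())

    def test_matches_brute_force_oracle_on_random_graphs(self, rng):
        for _ in range(20):
            G = random_graph(rng, n=rng.integers(5, 9))
            sc = network.betweenness(G)
            node_o, edge_o = brute_force_betweenness(G)
            for v in G.nodes:
                assert sc.node[v] == pytest.approx(node_o[v], abs=1e-9)
            for e in G.edges:
                key = tuple(sorted(e))
                got = sc.edge.get(e, sc.edge.get(e[::-1]))
                assert got == pytest.approx(edge_o[key], abs=1e-9)

    def test_invariant_under_uniform_weight_scaling(self, rng):
        G = random_graph(rng)
        sc1 = network.betweenness(G)
        H = G.copy()
        for u, v in H.edges:
            H[u][v]["weight"] *= 3.7
        sc2 = network.betweenness(H)
        for v in G.nodes:
            assert sc1.node[v] == pytest.approx(sc2.node[v], abs=1e-9)


class TestBackbone:
    def test_tree_keeps_all_edges(self, rng):
        G = nx.random_labeled_tree(8, seed=5)
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.uniform(0.5, 1.5))
        bb = network.backbone(G)
        assert set(map(frozenset, bb.edges)) == set(map(frozenset, G.edges))

    def test_always_connected_and_spanning(self, rng):
        for _ in range(10):
            G = random_graph(rng)
            bb = network.backbone(G)
            assert bb.is_connected
            assert set(bb.graph.nodes) == set(G.nodes)
            assert bb.graph.number_of_edges() >= G.number_of_nodes() - 1

    def test_matches_explicit_greedy_oracle(self, rng):
        G = random_graph(rng, n=6)
        sc = network.betweenness(G)
        bb = network.backbone(G, sc)
        # re-run the greedy rule independently
        def key(e):
            u, v = sorted(e)
            bt = sc.edge.get((u, v), sc.edge.get((v, u), 0.0))
            return (-bt, G[u][v]["weight"], (u, v))

        H = nx.Graph()
        H.add_nodes_from(G.nodes)
        kept = []
        for u, v in sorted(G.edges, key=key):
            H.add_edge(u, v)
            kept.append(tuple(sorted((u, v))))
            if nx.is_connected(H):
                break
        assert [tuple(sorted(e)) for e in bb.edges] == kept

    def test_disconnected_input_rejected(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        G.add_node(2)
        with pytest.raises(ValueError, match="disconnected"):
            network.backbone(G)


class TestKineticHub:
    def test_star_graph_center(self):
        G = nx.star_graph(5)
        nx.set_edge_attributes(G, 1.0, "weight")
        sc = network.betweenness(G)
        assert network.kinetic_hub(sc) == 0

    def test_path_graph_middle(self):
        G = nx.path_graph(5)
        nx.set_edge_attributes(G, 1.0, "weight")
        sc = network.betweenness(G)
        assert network.kinetic_hub(sc) == 2

    def test_matches_argmax_oracle(self, rng):
        for _ in range(10):
            G = random_graph(rng)
            sc = network.betweenness(G)
            hub = network.kinetic_hub(sc)
            assert sc.node[hub] == max(sc.node.values())

    def test_population_tie_break(self):
        sc = network.BetweennessScores(node={0: 1.0, 1: 1.0, 2: 0.5}, edge={})
        assert network.kinetic_hub(sc, populations={0: 0.1, 1: 0.4}) == 1


class TestApoHoloMetric:
    def test_endpoints_and_midpoint(self):
        assert network.apoholo_metric(0.0, 2.0) == -1.0
        assert network.apoholo_metric(2.0, 0.0) == 1.0
        assert network.apoholo_metric(1.3, 1.3) == 0.0

    def test_range(self, rng):
        for _ in range(50):
            a, h = rng.uniform(0, 5, size=2)
            if a + h == 0:
                continue
            assert -1.0 <= network.apoholo_metric(a, h) <= 1.0

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            network.apoholo_metric(0.0, 0.0)


class TestKLDivergence:
    def test_identical_distributions_zero(self, rng):
        P = rng.dirichlet(np.ones(10))
        assert network.kl_divergence(P, P) == 0.0

    def test_closed_form_half(self):
        assert network.kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(1000):
            P = rng.dirichlet(np.ones(6))
            Q = rng.dirichlet(np.ones(6))
            assert network.kl_divergence(P, Q) >= 0.0

    def test_infinite_without_pseudocount_and_finite_with(self):
        assert network.kl_divergence([0.5, 0.5], [1.0, 0.0]) == np.inf
        assert np.isfinite(network.kl_divergence([0.5, 0.5], [1.0, 0.0],
                                                 pseudocount=1e-6))

    def test_asymmetry(self):
        P, Q = [0.9, 0.1], [0.5, 0.5]
        assert network.kl_divergence(P, Q) != network.kl_divergence(Q, P)


class TestHubRobustness:
    def test_hub_agrees_between_independent_ensembles(self):
        """Same planted model sampled twice -> same kinetic hub."""
        from rexmap import msm, synthetic

        model = synthetic.make_ground_truth_msm(n_micro=200, n_macro=8,
                                                p_stay=0.95, seed=51)
        hubs = []
        for seed in (52, 53):
            paths = synthetic.sample_state_paths(model, 100, 3000, seed=seed)
            C = msm.count_transitions(paths.paths, lag=1, n_states=200)
            T = msm.estimate_T(C)
            pi = msm.stationary(T)
            lump = msm.anneal_lumping(T, msm.pcca(T, 8, pi=pi), pi=pi, seed=seed)
            Tm = msm.lump_T(T, pi, lump.lumping)
            pops = np.bincount(lump.lumping, weights=pi, minlength=8)
            # canonicalize macrostate identity by planted block content
            G = network.energy_graph(Tm.T, populations=pops)
            sc = network.betweenness(G)
            hub = network.kinetic_hub(sc, populations=dict(enumerate(pops)))
            # map hub back to the planted block it contains most of
            members = np.flatnonzero(lump.lumping == hub)
            hubs.append(np.bincount(model.lumping_true[members]).argmax())
        assert hubs[0] == hubs[1]
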
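"""Kinetic-network analytics on the macrostate transition matrix.

Transition probabilities are turned into additive "free-energy" edge weights
w_ij = -ln T_ij, so the most probable (maximum product-of-probabilities)
path between two macrostates is the weighted shortest path.  Betweenness
centrality over these shortest paths identifies kinetic hubs, and a greedy
backbone keeps the highest-betweenness edges until the network is connected
and spanning.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "BetweennessScores",
    "BackboneNetwork",
    "energy_graph",
    "betweenness",
    "backbone",
    "kinetic_hub",
    "apoholo_metric",
    "kl_divergence",
]


def energy_graph(T_macro, populations: np.ndarray = None,
                 mode: str = "symmetrized") -> nx.Graph:
    """Weighted kinetic graph with w_ij = -ln T_ij.

    Self-loops are dropped; pairs with zero transition probability get no
    edge.  ``mode="symmetrized"`` (default, matching an undirected network
    rendering) keeps an undirected edge weighted by the smaller of the two
    directed weights (i.e. the larger transition probability);
    ``mode="directed"`` keeps both directed edges.
    """
    M = T_macro.T if hasattr(T_macro, "lag") else np.asarray(T_macro, dtype=float)
    n = M.shape[0]
    G = nx.DiGraph() if mode == "directed" else nx.Graph()
    G.add_nodes_from(range(n))
    if populations is not None:
        for i in range(n):
            G.nodes[i]["population"] = float(populations[i])
    for i in range(n):
        for j in range(n):
            if i == j or M[i, j] <= 0:
                continue
            w = -np.log(M[i, j])
            if mode == "directed":
                G.add_edge(i, j, weight=w)
            elif not G.has_edge(i, j) or w < G[i][j]["weight"]:
                G.add_edge(i, j, weight=w)
    return G


@dataclass
class BetweennessScores:
    """Raw (unnormalized, fractional-multiplicity) betweenness values."""

    node: dict   # node -> score; path endpoints excluded
    edge: dict   # (u, v) -> score


def betweenness(graph: nx.Graph) -> BetweennessScores:
    """Node and edge betweenness over weighted shortest paths.

    Scores are raw sums of sigma_st(v)/sigma_st over source/target pairs
    (fractional when several shortest paths tie), endpoints excluded —
    the literal shortest-path-membership count.
    """
    node = nx.betweenness_centrality(graph, normalized=False, weight="weight")
    edge = nx.edge_betweenness_centrality(graph, normalized=False, weight="weight")
    return BetweennessScores(node=dict(node), edge=dict(edge))


@dataclass
class BackboneNetwork:
    """Greedy highest-betweenness spanning backbone."""

    edges: list          # retained edges, in descending betweenness order
    hub: int
    graph: nx.Graph

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(nx.Graph(self.graph))


def backbone(graph: nx.Graph, scores: BetweennessScores = None) -> BackboneNetwork:
    """Add edges in descending betweenness until the network spans and connects.

    Ties break deterministically: higher betweenness first, then lower edge
    weight, then lexicographic node pair.  The input graph must be
    connected (as an undirected graph).
    """
    U = nx.Graph(graph)  # undirected view for connectivity logic
    if not nx.is_connected(U):
        comps = [sorted(c) for c in nx.connected_components(U)]
        raise ValueError(f"input graph is disconnected: components {comps}")
    if scores is None:
        scores = betweenness(graph)

    def edge_key(e):
        u, v = e
        bt = scores.edge.get((u, v), scores.edge.get((v, u), 0.0))
        return (-bt, U[u][v]["weight"], tuple(sorted((u, v))))

    ordered = sorted(U.edges(), key=edge_key)
    B = nx.Graph()
    B.add_nodes_from(U.nodes(data=True))
    kept = []
    for u, v in ordered:
        B.add_edge(u, v, **U[u][v])
        kept.append((u, v))
        if B.number_of_nodes() == U.number_of_nodes() and nx.is_connected(B):
            break
    hub = kinetic_hub(scores, populations=nx.get_node_attributes(graph, "population"))
    return BackboneNetwork(edges=kept, hub=hub, graph=B)


def kinetic_hub(scores: BetweennessScores, populations: dict = None) -> int:
    """Most central node; ties break by larger population, then lower id."""
    def key(n):
        pop = (populations or {}).get(n, 0.0)
        return (-scores.node[n], -pop, n)

    return min(scores.node, key=key)


def apoholo_metric(rmsd_apo: float, rmsd_holo: float) -> float:
    """Normalized apo/holo axis: -1 = exactly apo-like, +1 = exactly holo-like.

    (rmsd_apo - rmsd_holo) / (rmsd_apo + rmsd_holo): a structure at zero
    RMSD from the apo reference scores -1, at zero from the holo reference
    +1, equidistant structures score 0.
    """
    if rmsd_apo < 0 or rmsd_holo < 0:
        raise ValueError("RMSD values must be non-negative")
    denom = rmsd_apo + rmsd_holo
    if denom == 0:
        raise ValueError("metric undefined when both RMSDs are zero")
    return (rmsd_apo - rmsd_holo) / denom


def kl_divergence(P, Q, pseudocount: float = 0.0) -> float:
    """Kullback-Leibler divergence sum p ln(p/q) in nats.

    A pseudocount is added to both distributions before renormalization.
    Without a pseudocount, q_i = 0 where p_i > 0 yields +inf explicitly.
    """
    P = np.asarray(P, dtype=float) + pseudocount
    Q = np.asarray(Q, dtype=float) + pseudocount
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same length")
    if (P < 0).any() or (Q < 0).any():
        raise ValueError("probabilities must be non-negative")
    P = P / P.sum()
    Q = Q / Q.sum()
    mask = P > 0
    if (Q[mask] == 0).any():
        return float("inf")
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))
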
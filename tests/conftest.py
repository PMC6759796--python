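"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import pytest

from netpharm import fixtures, ppi

#: Published per-node topology of the 16-protein hub PPI network
#: (degree, betweenness, avg shortest path length, closeness), printed
#: to 8 decimals.  Frozen reference for the reproduction tests.
EXPECTED_PPI_TOPOLOGY = {
    "VEGFA":  (7, 0.47407407, 1.3, 0.76923077),
    "STAT3":  (7, 0.21481481, 1.3, 0.76923077),
    "EGFR":   (6, 0.08888889, 1.4, 0.71428571),
    "JAK2":   (5, 0.01481481, 1.8, 0.55555556),
    "JAK1":   (5, 0.01481481, 1.8, 0.55555556),
    "IL6":    (5, 0.05925926, 1.5, 0.66666667),
    "KDR":    (3, 0.0, 2.0, 0.5),
    "FLT1":   (3, 0.0, 2.0, 0.5),
    "NRP2":   (3, 0.0, 2.0, 0.5),
    "HIF1A":  (3, 0.0, 1.7, 0.58823529),
    "STAT4":  (3, 0.0, 2.0, 0.5),
    "CYP1A1": (2, 1.0, 1.0, 1.0),
    "AHR":    (1, 0.0, 1.5, 0.66666667),
    "ATP1A1": (1, 0.0, 1.0, 1.0),
    "ATP1B1": (1, 0.0, 1.0, 1.0),
    "CYP2B6": (1, 0.0, 1.5, 0.66666667),
}


@pytest.fixture(scope="session")
def hub_ppi_edges():
    return fixtures.load_fixture_ppi()


@pytest.fixture(scope="session")
def hub_ppi_graph(hub_ppi_edges):
    return ppi.build_ppi_network(hub_ppi_edges)


# ---------------------------------------------------------------------------
# independent oracles (no networkx algorithms)

def bfs_distances(adj: dict, source):
    """Plain BFS distances over an adjacency dict."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(adj, s, t, d):
    """Enumerate every path of exactly the shortest length d from s to t."""
    paths = []

    def extend(path):
        u = path[-1]
        if len(path) - 1 == d:
            if u == t:
                paths.append(tuple(path))
            return
        for v in adj[u]:
            if v not in path:
                extend(path + [v])

    extend([s])
    return paths


def brute_force_topology(graph: nx.Graph):
    """Per-node (degree, betweenness, avgSPL, closeness) by exhaustive
    shortest-path enumeration, normalized within connected components."""
    adj = {v: sorted(graph.neighbors(v)) for v in graph.nodes()}
    out = {}
    seen = set()
    for start in sorted(adj):
        if start in seen:
            continue
        dist_map = {v: bfs_distances(adj, v) for v in bfs_distances(adj, start)}
        comp = sorted(dist_map)
        seen.update(comp)
        n = len(comp)
        raw_bet = {v: 0.0 for v in comp}
        for s, t in itertools.combinations(comp, 2):
            if t not in dist_map[s]:
                continue
            paths = _all_shortest_paths(adj, s, t, dist_map[s][t])
            sigma = len(paths)
            for v in comp:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                raw_bet[v] += through / sigma
        denom = (n - 1) * (n - 2) / 2
        for v in comp:
            deg = len(adj[v])
            if n == 1:
                out[v] = (deg, 0.0, float("nan"), 0.0)
            else:
                aspl = sum(dist_map[v][u] for u in comp if u != v) / (n - 1)
                bet = raw_bet[v] / denom if denom > 0 else 0.0
                out[v] = (deg, bet, aspl, 1.0 / aspl)
    return out


def brute_force_k_core(graph: nx.Graph, k: int) -> frozenset:
    """Union of all node subsets inducing min-degree >= k (the k-core)."""
    nodes = sorted(graph.nodes())
    best: set = set()
    for r in range(len(nodes), 0, -1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            if all(d >= k for _, d in sub.degree()):
                best |= set(subset)
        if best:
            # any valid subset of size r is contained in the union of all
            # valid subsets; smaller r cannot add nodes outside it
            break
    return frozenset(best)


def exact_hypergeom_upper(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), in exact rational arithmetic."""
    total = comb(N, n)
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i)
            for i in range(k, min(K, n) + 1)), total)


def graph_catalog(max_n: int = 8):
    """Small graphs sampled exhaustively by class up to ``max_n`` nodes:
    paths, cycles, stars, cliques, complete bipartite, all trees, and a
    seeded band of random graphs."""
    graphs = []
    for n in range(2, max_n + 1):
        graphs.append(nx.path_graph(n))
        graphs.append(nx.complete_graph(n))
        if n >= 3:
            graphs.append(nx.cycle_graph(n))
            graphs.append(nx.star_graph(n - 1))
        for a in range(1, n // 2 + 1):
            graphs.append(nx.complete_bipartite_graph(a, n - a))
        for t in nx.nonisomorphic_trees(n):
            graphs.append(t)
        for p in (0.2, 0.5, 0.8):
            for seed in range(3):
                graphs.append(nx.gnp_random_graph(n, p, seed=seed))
    return [nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes()}) for g in graphs]
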
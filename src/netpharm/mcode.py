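"""Molecular Complex Detection (MCODE) graph clustering, from scratch.

MCODE finds densely connected regions of a network in three stages:

1. **Vertex weighting.**  Each vertex is scored by the density of the
   highest k-core of its closed neighborhood: w(v) = k_max * density of
   that core, where density = 2m / (n(n-1)).  High weight marks vertices
   embedded in locally dense, clique-like regions.
2. **Cluster prediction.**  Starting from the highest-weight unassigned
   vertex, a cluster grows outward breadth-first, admitting neighbors
   whose weight is at least ``seed_weight * (1 - node_score_cutoff)``.
   A vertex below the threshold blocks traversal through it, and each
   vertex belongs to at most one cluster.
3. **Post-processing.**  Clusters without a 2-core are discarded
   (unless fluff is on); the optional *haircut* strips members with a
   single connection inside the cluster; the optional *fluff* step adds
   boundary neighbors whose closed-neighborhood density exceeds
   ``fluff_density``.

Cluster score = density * size of the cluster's induced subgraph, so a
clique K_n scores exactly n.  All iteration orders are sorted, so the
output is independent of node insertion order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx


@dataclass(frozen=True)
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core_threshold: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0,1]")
        for name in ("degree_cutoff", "k_core_threshold", "max_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fluff_density <= 1.0:
            raise ValueError("fluff_density must be in [0,1]")


@dataclass(frozen=True)
class Cluster:
    """A predicted dense subgraph: seed vertex, member set, and
    density*size score of the induced subgraph."""
    seed: str
    members: frozenset
    score: float

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# primitives

def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph where every vertex keeps degree >= k.

    Computed by iteratively pruning low-degree vertices to a fixpoint;
    may be empty.  Self-loops are ignored.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    g = nx.Graph()
    g.add_nodes_from(graph.nodes())
    g.add_edges_from((u, v) for u, v in graph.edges() if u != v)
    while True:
        drop = [v for v, d in g.degree() if d < k]
        if not drop:
            return g
        g.remove_nodes_from(drop)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _highest_k_core(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """(k_max, core) for the highest non-empty k-core of ``graph``."""
    k, core = 0, k_core(graph, 0)
    while True:
        nxt = k_core(core, k + 1)
        if nxt.number_of_nodes() == 0:
            return k, core
        k, core = k + 1, nxt


def vertex_weight(graph: nx.Graph, node) -> float:
    """MCODE weight of a vertex: k_max * density of the highest k-core of
    its closed neighborhood.  Isolated vertices weigh 0."""
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    nbrs = set(graph.neighbors(node)) - {node}
    if not nbrs:
        return 0.0
    h = graph.subgraph(nbrs | {node})
    k_max, core = _highest_k_core(h)
    return k_max * _density(core)


def _weights(graph: nx.Graph, params: MCODEParams) -> dict:
    return {
        v: (vertex_weight(graph, v) if graph.degree(v) >= params.degree_cutoff else 0.0)
        for v in graph.nodes()
    }


# ---------------------------------------------------------------------------
# prediction

def _score(graph: nx.Graph, members) -> float:
    sub = graph.subgraph(members)
    return _density(sub) * sub.number_of_nodes()


def predict_clusters(graph: nx.Graph, params: MCODEParams | None = None) -> list[Cluster]:
    """Stage 2: grow non-overlapping clusters from high-weight seeds.

    Returns clusters ordered by score descending (ties: larger first,
    then lexicographic seed id).  An edgeless graph yields no clusters.
    """
    params = params or MCODEParams()
    g = nx.Graph()
    g.add_nodes_from(graph.nodes())
    g.add_edges_from((u, v) for u, v in graph.edges() if u != v)
    weights = _weights(g, params)

    order = sorted(g.nodes(), key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    clusters = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for v in sorted(frontier, key=str):
                for u in sorted(g.neighbors(v), key=str):
                    if u in members or u in assigned:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        assigned |= members
        clusters.append(Cluster(seed=seed, members=frozenset(members),
                                score=_score(g, members)))
    return sorted(clusters, key=lambda c: (-c.score, -c.size, str(c.seed)))


# ---------------------------------------------------------------------------
# post-processing

def postprocess(clusters, graph: nx.Graph, params: MCODEParams | None = None) -> list[Cluster]:
    """Stage 3: 2-core filter, optional fluff, optional haircut.

    With fluff off the output members are a subset of the input members;
    the 2-core requirement drops tree-like clusters (e.g. a single edge).
    """
    params = params or MCODEParams()
    out = []
    for cl in clusters:
        members = set(cl.members)
        if not params.fluff:
            core = k_core(graph.subgraph(members), params.k_core_threshold)
            if core.number_of_nodes() == 0:
                continue
        if params.fluff:
            for v in sorted(cl.members, key=str):
                for u in sorted(graph.neighbors(v), key=str):
                    if u in members:
                        continue
                    nbh = set(graph.neighbors(u)) | {u}
                    if _density(graph.subgraph(nbh)) > params.fluff_density:
                        members.add(u)
        if params.haircut:
            core = k_core(graph.subgraph(members), 2)
            members = set(core.nodes())
            if not members:
                continue
        out.append(replace(cl, members=frozenset(members),
                           score=_score(graph, members)))
    return sorted(out, key=lambda c: (-c.score, -c.size, str(c.seed)))


def find_clusters(graph: nx.Graph, params: MCODEParams | None = None) -> list[Cluster]:
    """Full MCODE run: weighting, prediction, post-processing."""
    params = params or MCODEParams()
    return postprocess(predict_clusters(graph, params), graph, params)


def write_clusters_tsv(clusters, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tscore\tsize\tseed\tmembers\n")
        for i, cl in enumerate(clusters, start=1):
            members = ",".join(sorted(cl.members, key=str))
            fh.write(f"{i}\t{cl.score:.4f}\t{cl.size}\t{cl.seed}\t{members}\n")
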
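"""Per-node topological metrics and hub extraction.

Conventions follow Cytoscape's NetworkAnalyzer on undirected simple
graphs, computed *within each connected component*:

* degree — number of distinct neighbors;
* average shortest path length — mean BFS distance to the other members
  of the node's component (undefined for isolated nodes);
* closeness centrality — reciprocal of the average shortest path length
  (0 for isolated nodes);
* betweenness centrality — fraction of pairwise shortest paths through
  the node, normalized by (n-1)(n-2)/2 with n the component size.

Per-component normalization matters: a node that bridges a 3-node
component has betweenness exactly 1 regardless of how large the rest of
the graph is.  Confidence scores, where present, are never used as path
weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

TOPOLOGY_COLUMNS = ["degree", "betweenness", "avg_shortest_path_length", "closeness"]

#: Header used when exporting a topology table, matching NetworkAnalyzer.
EXPORT_HEADER = ["Genes/proteins", "Degree", "Betweenness centrality",
                 "Average shortest path length", "Closeness centrality"]


@dataclass(frozen=True)
class HubThreshold:
    """Degree cutoff for hub extraction: strictly greater than the mean
    number of distinct neighbors over all nodes."""
    mean_neighbors: float
    rule: str = "strict-greater"


def _simple(graph: nx.Graph) -> nx.Graph:
    """Collapse duplicate edges / self-loops into a simple undirected graph."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes())
    g.add_edges_from((u, v) for u, v in graph.edges() if u != v)
    return g


def connected_components(graph: nx.Graph) -> list[frozenset]:
    """Connected components, largest first (ties: by smallest member id)."""
    comps = [frozenset(c) for c in nx.connected_components(_simple(graph))]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))


def node_topology(graph: nx.Graph) -> pd.DataFrame:
    """Compute the four per-node metrics.

    Returns a DataFrame indexed by node with columns ``degree``,
    ``betweenness``, ``avg_shortest_path_length`` and ``closeness``.
    Isolated nodes get avg_shortest_path_length = NaN, closeness 0 and
    betweenness 0.
    """
    g = _simple(graph)
    records = {}
    for comp in connected_components(g):
        sub = g.subgraph(comp)
        n = len(comp)
        bc = nx.betweenness_centrality(sub, normalized=True) if n > 2 else {v: 0.0 for v in comp}
        for v in comp:
            if n == 1:
                aspl, clo = math.nan, 0.0
            else:
                dists = nx.single_source_shortest_path_length(sub, v)
                aspl = sum(d for u, d in dists.items() if u != v) / (n - 1)
                clo = 1.0 / aspl
            records[v] = (sub.degree(v), bc[v], aspl, clo)
    df = pd.DataFrame.from_dict(records, orient="index", columns=TOPOLOGY_COLUMNS)
    df.index.name = "node"
    return df.sort_index()


def extract_major_hub_network(graph: nx.Graph) -> tuple[nx.Graph, HubThreshold]:
    """Induced subgraph on nodes whose degree strictly exceeds the mean
    number of neighbors.

    In a simple graph the mean neighbor count equals 2|E|/|V|; the
    threshold is reported alongside the subgraph.  In a k-regular graph
    nothing passes the strict inequality and the result is empty.
    """
    g = _simple(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot extract hubs from an empty graph")
    mean_neighbors = sum(d for _, d in g.degree()) / g.number_of_nodes()
    keep = [v for v, d in g.degree() if d > mean_neighbors]
    return g.subgraph(keep).copy(), HubThreshold(mean_neighbors=mean_neighbors)


def rank_nodes(table: pd.DataFrame) -> pd.DataFrame:
    """Order a topology table by degree desc, then betweenness desc, then
    node id ascending (stable)."""
    if table.empty:
        raise ValueError("cannot rank an empty table")
    return (table.sort_index()
                 .sort_values(["degree", "betweenness"],
                              ascending=[False, False], kind="mergesort"))


def write_topology_tsv(table: pd.DataFrame, path) -> None:
    """Export with NetworkAnalyzer-style headers, floats to 8 decimals."""
    out = table.copy()
    out.insert(0, EXPORT_HEADER[0], out.index)
    out.columns = EXPORT_HEADER
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EXPORT_HEADER) + "\n")
        for row in out.itertuples(index=False):
            name, deg, bet, aspl, clo = row
            aspl_s = "" if isinstance(aspl, float) and math.isnan(aspl) else f"{aspl:.8f}"
            fh.write(f"{name}\t{int(deg)}\t{bet:.8f}\t{aspl_s}\t{clo:.8f}\n")
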
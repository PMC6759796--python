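"""Consensus hub targets and the confidence-filtered PPI subnetwork.

Hub targets are defined by agreement of two independent analyses of the
compound-target network: the degree-threshold topological hubs and the
members of the top MCODE cluster.  Their database interactions are then
filtered at the highest-confidence score (>= 0.9 by default) and
assembled into a protein-protein interaction graph in which every node
is either a *hub* (one of the consensus targets) or a *predicted
functional* partner pulled in by an interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import io
from .symbols import normalize_symbol

HIGHEST_CONFIDENCE = 0.9


@dataclass(frozen=True)
class HubReport:
    """The hub-derivation audit trail."""
    topological_hubs: frozenset
    cluster_targets: frozenset
    consensus: frozenset
    predicted_functional: frozenset

    def __post_init__(self) -> None:
        if self.consensus != self.topological_hubs & self.cluster_targets:
            raise ValueError("consensus must equal topological_hubs & cluster_targets")
        if self.predicted_functional & self.consensus:
            raise ValueError("predicted_functional must be disjoint from consensus")


def intersect_hubs(topological_hubs, cluster_members, targets=None) -> frozenset[str]:
    """Consensus hubs: topological hubs that also sit in the cluster.

    ``cluster_members`` may mix compound ids and target symbols; only
    entries that normalize to a symbol in ``targets`` (when given) or in
    ``topological_hubs`` survive.  Symbols are normalized on both sides.
    """
    topo = frozenset(normalize_symbol(s) for s in topological_hubs)
    cluster = frozenset(normalize_symbol(s) for s in cluster_members)
    out = topo & cluster
    if targets is not None:
        out &= frozenset(normalize_symbol(s) for s in targets)
    return out


def filter_ppi_edges(edges: pd.DataFrame, min_score: float = HIGHEST_CONFIDENCE) -> pd.DataFrame:
    """Keep edges with confidence score >= ``min_score`` (inclusive),
    preserving input order."""
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must be in [0,1]")
    return edges[edges["score"] >= min_score].reset_index(drop=True)


def build_ppi_network(edges: pd.DataFrame, hub_symbols=frozenset()) -> nx.Graph:
    """Simple undirected PPI graph from a scored edge table.

    Scores become edge attributes (never path weights); each node gets a
    ``role`` attribute: ``hub`` when in ``hub_symbols``, else
    ``predicted_functional``.  A duplicate unordered pair with
    conflicting scores is an error; exact duplicates collapse.
    """
    hubs = frozenset(normalize_symbol(s) for s in hub_symbols)
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        u, v = normalize_symbol(row.node1), normalize_symbol(row.node2)
        if u == v:
            raise ValueError(f"self-interaction {u!r}")
        if g.has_edge(u, v) and g[u][v]["score"] != float(row.score):
            raise ValueError(
                f"conflicting scores for pair {u}-{v}: "
                f"{g[u][v]['score']} vs {row.score}")
        g.add_edge(u, v, score=float(row.score))
    for n in g.nodes():
        g.nodes[n]["role"] = "hub" if n in hubs else "predicted_functional"
    return g


def make_hub_report(topological_hubs, cluster_members, ppi_nodes) -> HubReport:
    """Assemble the HubReport: consensus hubs plus the PPI partners that
    are not themselves consensus targets."""
    topo = frozenset(normalize_symbol(s) for s in topological_hubs)
    cluster = frozenset(normalize_symbol(s) for s in cluster_members)
    consensus = topo & cluster
    predicted = frozenset(normalize_symbol(s) for s in ppi_nodes) - consensus
    return HubReport(topological_hubs=topo, cluster_targets=cluster,
                     consensus=consensus, predicted_functional=predicted)


def write_ppi_sif(graph: nx.Graph, path) -> None:
    io.write_sif(sorted(tuple(sorted(e)) for e in graph.edges()), path, relation="pp")
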
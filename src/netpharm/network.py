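"""Consensus target sets and the bipartite compound-target (C-T) network.

The C-T network links herbal components to the disease-relevant targets
they putatively bind: an undirected bipartite graph whose target side is
the consensus between the compounds' putative targets and the disease
target list.  Edges are unweighted; the asserting source databases are
kept as an edge annotation for traceability only.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from . import io
from .symbols import TargetSet, normalize_symbol


class BipartiteNetwork:
    """Undirected bipartite graph of compound and target nodes.

    Wraps a :class:`networkx.Graph` whose nodes carry a ``part``
    attribute in {"compound", "target"}; edges run only between parts.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self.validate()

    # -- construction ------------------------------------------------------
    def add_edge(self, compound: str, target: str, **attrs) -> None:
        if compound == target:
            raise ValueError(f"self-loop on {compound!r}")
        self.graph.add_node(compound, part="compound")
        self.graph.add_node(target, part="target")
        self.graph.add_edge(compound, target, **attrs)

    # -- views -------------------------------------------------------------
    @property
    def compound_nodes(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d.get("part") == "compound")

    @property
    def target_nodes(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d.get("part") == "target")

    @property
    def edges(self) -> frozenset[frozenset]:
        return frozenset(frozenset(e) for e in self.graph.edges())

    def validate(self) -> None:
        parts = nx.get_node_attributes(self.graph, "part")
        for n in self.graph.nodes():
            if parts.get(n) not in ("compound", "target"):
                raise ValueError(f"node {n!r} lacks a declared part")
        for u, v in self.graph.edges():
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if parts[u] == parts[v]:
                raise ValueError(f"edge within one part: {u!r}-{v!r}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (self.compound_nodes == other.compound_nodes
                and self.target_nodes == other.target_nodes
                and self.edges == other.edges)

    def __repr__(self) -> str:
        return (f"BipartiteNetwork({len(self.compound_nodes)} compounds, "
                f"{len(self.target_nodes)} targets, {self.graph.number_of_edges()} edges)")


# ---------------------------------------------------------------------------
# target-set arithmetic

def union_compound_targets(ct_map: pd.DataFrame, name: str = "compound-union") -> TargetSet:
    """Deduplicated union of target symbols over all compounds and source tags."""
    if ct_map.empty:
        raise ValueError("compound-target table is empty")
    return TargetSet(name=name, symbols=frozenset(ct_map["target_symbol"].map(normalize_symbol)),
                     provenance="union of compound-target assertions")


def intersect_targets(compound_union: TargetSet, disease: TargetSet,
                      name: str = "consensus") -> TargetSet:
    """Consensus targets: compounds' putative targets that are also disease targets."""
    return compound_union.intersect(disease, name=name)


def build_ct_network(ct_map: pd.DataFrame, consensus: TargetSet) -> BipartiteNetwork:
    """Build the C-T network restricted to consensus targets.

    An edge (compound, target) exists iff any source asserts the pair and
    the target is in the consensus set; assertions from multiple
    databases collapse to a single edge carrying the sorted tag list.
    Compounds left without any consensus target are dropped.
    """
    net = BipartiteNetwork()
    if len(consensus) == 0:
        warnings.warn("empty consensus set: returning an empty C-T network", stacklevel=2)
        return net
    sources: dict[tuple[str, str], set[str]] = {}
    for row in ct_map.itertuples(index=False):
        t = normalize_symbol(row.target_symbol)
        if t in consensus.symbols:
            sources.setdefault((row.compound_id, t), set()).add(str(row.source_tag))
    for (c, t), tags in sorted(sources.items()):
        net.add_edge(c, t, sources=",".join(sorted(tags)))
    net.validate()
    return net


# ---------------------------------------------------------------------------
# readers/writers for the bipartite network

def write_edge_tsv(net: BipartiteNetwork, path) -> None:
    rows = []
    for u, v in net.graph.edges():
        if net.graph.nodes[u]["part"] == "compound":
            rows.append((u, v))
        else:
            rows.append((v, u))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound\ttarget\n")
        for c, t in sorted(rows):
            fh.write(f"{c}\t{t}\n")


def read_edge_tsv(path) -> BipartiteNetwork:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["compound", "target"]:
        raise io.FormatError(f"{path}: expected header 'compound\\ttarget'")
    net = BipartiteNetwork()
    for row in df.itertuples(index=False):
        net.add_edge(row.compound, row.target)
    return net


def write_sif(net: BipartiteNetwork, path) -> None:
    """SIF with relation word ``ct``; compound always in the first column."""
    pairs = []
    for u, v in net.graph.edges():
        if net.graph.nodes[u]["part"] == "compound":
            pairs.append((u, v))
        else:
            pairs.append((v, u))
    io.write_sif(sorted(pairs), path, relation="ct")


def read_sif(path) -> BipartiteNetwork:
    net = BipartiteNetwork()
    for lineno, (a, rel, b) in enumerate(io.read_sif(path), start=1):
        if rel != "ct":
            raise io.FormatError(f"{path}: line {lineno}: expected relation 'ct', got {rel!r}")
        net.add_edge(a, b)
    return net


def write_graphml(net: BipartiteNetwork, path) -> None:
    io.write_graphml(net.graph, path)


def read_graphml(path) -> BipartiteNetwork:
    g = io.read_graphml(path)
    for n, d in g.nodes(data=True):
        if d.get("part") not in ("compound", "target"):
            raise io.FormatError(f"{path}: node {n!r} lacks a bipartite part attribute")
    return BipartiteNetwork(g)
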
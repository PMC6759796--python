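"""Readers and writers for the pipeline's interchange formats.

All formats are plain UTF-8 text, tab-delimited where tabular:

* scored edge table — TSV with header ``node1  node2  score``
  (a STRING-export stand-in; an optional ``relation`` column is
  tolerated on input and ignored);
* SIF — ``node1<TAB>relation<TAB>node2``, relation ``ct`` for
  compound-target edges and ``pp`` for protein-protein edges;
* GraphML — via networkx, with a ``part`` node attribute for
  bipartite graphs;
* GMT — Broad convention: ``term<TAB>description<TAB>member...``;
* gene lists — one symbol per line;
* concentration profiles — CSV ``subject,time_min,conc``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from .symbols import normalize_symbol

SCORED_EDGE_COLUMNS = ["node1", "node2", "score"]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# scored edge tables (STRING-style)

def read_scored_edges(path) -> pd.DataFrame:
    """Read a scored-edge TSV into a (node1, node2, score) DataFrame.

    Symbols are normalized; a ``relation`` column, if present, is dropped.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("node1", "node2", "score") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[SCORED_EDGE_COLUMNS].copy()
    df["node1"] = df["node1"].map(normalize_symbol)
    df["node2"] = df["node2"].map(normalize_symbol)
    df["score"] = df["score"].astype(float)
    bad = df[(df["score"] < 0) | (df["score"] > 1)]
    if not bad.empty:
        raise FormatError(f"{path}: scores outside [0,1] at data row(s) {list(bad.index)}")
    return df


def write_scored_edges(df: pd.DataFrame, path) -> None:
    df[SCORED_EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SIF

def write_sif(edges, path, relation: str) -> None:
    """Write (u, v) edge pairs as a SIF file with one fixed relation word."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{relation}\t{v}\n")


def read_sif(path) -> list[tuple[str, str, str]]:
    """Read SIF rows as (node1, relation, node2) triples.

    Raises :class:`FormatError` naming the 1-based line number on a
    malformed row.
    """
    triples = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
            triples.append((parts[0], parts[1], parts[2]))
    return triples


# ---------------------------------------------------------------------------
# GraphML

def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    for node, data in g.nodes(data=True):
        part = data.get("part")
        if part is not None and part not in ("compound", "target"):
            raise FormatError(f"{path}: node {node!r} has unknown part {part!r}")
    return nx.Graph(g)


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path) -> list[tuple[str, str, frozenset[str]]]:
    """Read a GMT file into (term_id, description, member-set) tuples."""
    terms = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT rows need term, description and >=1 member")
            term, desc, members = parts[0], parts[1], parts[2:]
            members = frozenset(normalize_symbol(m) for m in members if m.strip())
            if not members:
                raise FormatError(f"{path}: line {lineno}: term {term!r} has no members")
            terms.append((term, desc, members))
    return terms


def write_gmt(terms, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, desc, members in terms:
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# flat gene lists and concentration profiles

def read_gene_list(path) -> frozenset[str]:
    """Read a one-symbol-per-line file into a normalized set."""
    with open(path, encoding="utf-8") as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    return frozenset(normalize_symbol(s) for s in symbols)


def write_gene_list(symbols, path) -> None:
    Path(path).write_text("\n".join(sorted(symbols)) + "\n", encoding="utf-8")


def read_concentrations(path) -> pd.DataFrame:
    """Read a subject,time_min,conc CSV (extra columns tolerated)."""
    df = pd.read_csv(path)
    missing = [c for c in ("subject", "time_min", "conc") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df["conc"] < 0).any():
        raise FormatError(f"{path}: negative concentrations present")
    return df


def write_concentrations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_compound_target_table(path) -> pd.DataFrame:
    """Read a compound->target assertion TSV (compound_id, target_symbol, source_tag)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("compound_id", "target_symbol", "source_tag") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.copy()
    df["target_symbol"] = df["target_symbol"].map(normalize_symbol)
    return df


def write_compound_target_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
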
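"""Knowledge-graph data model with GraphML and TSV readers/writers.

Nodes are typed biological entities identified by a URI; edges are typed
relations (metaedges) carrying an optional confidence score in [0, 1] and
free-form properties.  Undirected metaedges are canonicalized with their
endpoints in lexicographic URI order; duplicate entries for the same
(source, target, metaedge) triple are merged keeping the maximum score and
the union of tissue sets.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import networkx as nx
import pandas as pd

from .schema import (
    METAEDGES,
    NODE_TYPE_ABBREV,
    Metaedge,
    SchemaError,
    metaedge_by_abbrev,
)

__all__ = [
    "Node",
    "Edge",
    "KnowledgeGraph",
    "load_graphml",
    "save_graphml",
    "load_tsv",
    "save_tsv",
    "metaedge_stats",
    "schema_validate",
]

_NUMERIC_NODE_PROPS = {"RVIS", "GDI"}


@dataclass(frozen=True)
class Node:
    uri: str
    node_type: str
    properties: Tuple[Tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if not self.uri:
            raise SchemaError("node uri must be non-empty")
        if self.node_type not in NODE_TYPE_ABBREV:
            raise SchemaError(
                f"unknown node type {self.node_type!r} for node {self.uri!r}"
            )

    @property
    def props(self) -> Dict[str, object]:
        return dict(self.properties)


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    metaedge: str  # abbreviation, e.g. "GpG"
    score: Optional[float] = None
    tissues: Optional[frozenset] = None  # "in" property of GeG edges
    properties: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        metaedge_by_abbrev(self.metaedge)

    @property
    def meta(self) -> Metaedge:
        return METAEDGES[self.metaedge]

    def other(self, uri: str) -> str:
        return self.target if uri == self.source else self.source

    def key(self) -> Tuple[str, str, str]:
        return (self.source, self.target, self.metaedge)


class KnowledgeGraph:
    """Typed multigraph: at most one edge per (source, target, metaedge)."""

    def __init__(self) -> None:
        self.nodes: Dict[str, Node] = {}
        self._edges: Dict[Tuple[str, str, str], Edge] = {}
        self._adjacency: Optional[Dict[str, List[Tuple[Edge, str, bool]]]] = None

    # -- construction -------------------------------------------------
    def add_node(self, node: Node) -> None:
        self.nodes[node.uri] = node
        self._adjacency = None

    def add_edge(self, edge: Edge) -> None:
        """Insert an edge, canonicalizing and merging duplicates (max score)."""
        meta = edge.meta
        src, tgt = edge.source, edge.target
        if not meta.directed and tgt < src:
            src, tgt = tgt, src
            edge = Edge(src, tgt, edge.metaedge, edge.score, edge.tissues,
                        edge.properties)
        key = edge.key()
        prev = self._edges.get(key)
        if prev is not None:
            score = _max_opt(prev.score, edge.score)
            tissues = _union_opt(prev.tissues, edge.tissues)
            props = dict(prev.properties)
            props.update(dict(edge.properties))
            edge = Edge(src, tgt, edge.metaedge, score, tissues,
                        tuple(sorted(props.items())))
        self._edges[key] = edge
        self._adjacency = None

    # -- views --------------------------------------------------------
    @property
    def edges(self) -> List[Edge]:
        return list(self._edges.values())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def adjacency(self, uri: str) -> List[Tuple[Edge, str, bool]]:
        """Incident edges of ``uri`` as (edge, other endpoint, forward flag).

        ``forward`` is True when the edge is traversed from its declared
        source to its declared target (always True when leaving the source
        of an undirected, canonicalized edge).
        """
        if self._adjacency is None:
            adj: Dict[str, List[Tuple[Edge, str, bool]]] = {
                u: [] for u in self.nodes
            }
            for e in self._edges.values():
                adj.setdefault(e.source, []).append((e, e.target, True))
                if e.target != e.source:
                    adj.setdefault(e.target, []).append((e, e.source, False))
            self._adjacency = adj
        return self._adjacency.get(uri, [])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self.nodes == other.nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"KnowledgeGraph({self.n_nodes} nodes, {self.n_edges} edges)"


def _max_opt(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None:
        return b
    if b is None:
        return a
    return max(a, b)


def _union_opt(a: Optional[frozenset], b: Optional[frozenset]):
    if a is None:
        return b
    if b is None:
        return a
    return a | b


# ---------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------

def save_graphml(kg: KnowledgeGraph, path) -> None:
    g = nx.DiGraph()
    for node in kg.nodes.values():
        attrs = {"node_type": node.node_type}
        for k, v in node.properties:
            attrs[k] = v
        g.add_node(node.uri, **attrs)
    for e in kg.edges:
        attrs: Dict[str, object] = {"metaedge": e.metaedge}
        if e.score is not None:
            attrs["score"] = float(e.score)
        if e.tissues is not None:
            attrs["in"] = "|".join(sorted(e.tissues))
        for k, v in e.properties:
            attrs[k] = v
        g.add_edge(e.source, e.target, **attrs)
    nx.write_graphml(g, path)


def load_graphml(path) -> KnowledgeGraph:
    g = nx.read_graphml(path)
    kg = KnowledgeGraph()
    for uri, attrs in g.nodes(data=True):
        attrs = dict(attrs)
        node_type = attrs.pop("node_type", None)
        if node_type is None:
            raise SchemaError(f"node {uri!r} lacks a node_type attribute")
        props = []
        for k, v in attrs.items():
            if k in _NUMERIC_NODE_PROPS and not isinstance(v, numbers.Real):
                v = float(v)
            props.append((k, v))
        kg.add_node(Node(str(uri), node_type, tuple(sorted(props))))
    for u, v, attrs in g.edges(data=True):
        attrs = dict(attrs)
        metaedge = attrs.pop("metaedge", None)
        if metaedge is None:
            raise SchemaError(f"edge {u!r}->{v!r} lacks a metaedge attribute")
        score = attrs.pop("score", None)
        tissues = attrs.pop("in", None)
        if tissues is not None:
            tissues = frozenset(str(tissues).split("|")) if tissues else frozenset()
        props = tuple(sorted((k, str(w)) for k, w in attrs.items()))
        kg.add_edge(
            Edge(str(u), str(v), str(metaedge),
                 None if score is None else float(score), tissues, props)
        )
    _check_endpoints(kg)
    return kg


# ---------------------------------------------------------------------
# TSV (Neo4j-import dialect: header row, tab separated, pipe-joined sets)
# ---------------------------------------------------------------------

_NODE_COLUMNS = {"uri": "uri", "type": "type"}
_EDGE_COLUMNS = {"source": "source", "target": "target",
                 "metaedge": "metaedge", "score": "score"}


def load_tsv(node_file, edge_file, column_map: Optional[Mapping[str, str]] = None
             ) -> KnowledgeGraph:
    """Read a graph from node/edge TSV files.

    ``column_map`` remaps the canonical column names (uri, type, source,
    target, metaedge, score) onto the headers actually present in the files.
    Any extra column is kept as a property; empty cells mean "absent".
    """
    cmap = dict(column_map or {})
    kg = KnowledgeGraph()
    nodes = pd.read_csv(node_file, sep="\t", dtype=str, keep_default_na=False)
    ucol = cmap.get("uri", "uri")
    tcol = cmap.get("type", "type")
    for _, row in nodes.iterrows():
        props = []
        for col in nodes.columns:
            if col in (ucol, tcol) or row[col] == "":
                continue
            val: object = row[col]
            if col in _NUMERIC_NODE_PROPS:
                val = float(val)
            props.append((col, val))
        kg.add_node(Node(row[ucol], row[tcol], tuple(sorted(props))))

    edges = pd.read_csv(edge_file, sep="\t", dtype=str, keep_default_na=False)
    scol = cmap.get("source", "source")
    gcol = cmap.get("target", "target")
    mcol = cmap.get("metaedge", "metaedge")
    kcol = cmap.get("score", "score")
    missing: List[str] = []
    for _, row in edges.iterrows():
        for end in (row[scol], row[gcol]):
            if end not in kg.nodes:
                missing.append(end)
        score = None
        if kcol in edges.columns and row[kcol] != "":
            score = float(row[kcol])
        tissues = None
        if "in" in edges.columns and row["in"] != "":
            tissues = frozenset(row["in"].split("|"))
        props = tuple(
            sorted(
                (col, row[col])
                for col in edges.columns
                if col not in (scol, gcol, mcol, kcol, "in") and row[col] != ""
            )
        )
        kg.add_edge(Edge(row[scol], row[gcol], row[mcol], score, tissues, props))
    if missing:
        raise SchemaError(
            "edge file references nodes absent from the node file: "
            + ", ".join(sorted(set(missing)))
        )
    _check_endpoints(kg)
    return kg


def save_tsv(kg: KnowledgeGraph, node_file, edge_file) -> None:
    prop_cols = sorted({k for n in kg.nodes.values() for k, _ in n.properties})
    rows = []
    for n in sorted(kg.nodes.values(), key=lambda n: n.uri):
        row = {"uri": n.uri, "type": n.node_type}
        props = n.props
        for c in prop_cols:
            row[c] = props.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=["uri", "type", *prop_cols]).to_csv(
        node_file, sep="\t", index=False
    )

    eprop_cols = sorted({k for e in kg.edges for k, _ in e.properties})
    rows = []
    for e in sorted(kg.edges, key=Edge.key):
        row = {
            "source": e.source,
            "target": e.target,
            "metaedge": e.metaedge,
            "score": "" if e.score is None else e.score,
            "in": "" if e.tissues is None else "|".join(sorted(e.tissues)),
        }
        props = dict(e.properties)
        for c in eprop_cols:
            row[c] = props.get(c, "")
        rows.append(row)
    pd.DataFrame(
        rows, columns=["source", "target", "metaedge", "score", "in", *eprop_cols]
    ).to_csv(edge_file, sep="\t", index=False)


def _check_endpoints(kg: KnowledgeGraph) -> None:
    report = schema_validate(kg)
    if report:
        raise SchemaError("; ".join(report))


# ---------------------------------------------------------------------
# Statistics and validation
# ---------------------------------------------------------------------

def metaedge_stats(kg: KnowledgeGraph) -> pd.DataFrame:
    """Per-metaedge edge / distinct source / distinct target counts."""
    rows = []
    by_meta: Dict[str, List[Edge]] = {}
    for e in kg.edges:
        by_meta.setdefault(e.metaedge, []).append(e)
    for abbrev in sorted(by_meta, key=lambda a: -len(by_meta[a])):
        group = by_meta[abbrev]
        meta = METAEDGES[abbrev]
        if meta.directed:
            srcs = {e.source for e in group}
            tgts = {e.target for e in group}
        else:
            incident = {u for e in group for u in (e.source, e.target)}
            srcs = tgts = incident
        rows.append(
            {"metaedge": abbrev, "n_edges": len(group),
             "n_sources": len(srcs), "n_targets": len(tgts)}
        )
    return pd.DataFrame(rows, columns=["metaedge", "n_edges", "n_sources",
                                       "n_targets"])


def schema_validate(kg: KnowledgeGraph) -> List[str]:
    """List every schema violation; an empty list means the graph conforms."""
    report: List[str] = []
    for e in kg.edges:
        for end in (e.source, e.target):
            if end not in kg.nodes:
                report.append(f"edge {e.key()}: endpoint {end!r} not in graph")
        meta = e.meta
        src = kg.nodes.get(e.source)
        tgt = kg.nodes.get(e.target)
        ok_forward = (
            src is not None and tgt is not None
            and src.node_type == meta.source_type
            and tgt.node_type == meta.target_type
        )
        ok_reverse = (
            not meta.directed
            and src is not None and tgt is not None
            and src.node_type == meta.target_type
            and tgt.node_type == meta.source_type
        )
        if src is not None and tgt is not None and not (ok_forward or ok_reverse):
            report.append(
                f"edge {e.key()}: endpoint types "
                f"({src.node_type}, {tgt.node_type}) do not match metaedge "
                f"{meta.abbreviation} ({meta.source_type}, {meta.target_type})"
            )
        if e.score is not None and not (0.0 <= e.score <= 1.0):
            report.append(f"edge {e.key()}: score {e.score} outside [0, 1]")
    return report
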
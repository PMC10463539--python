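"""Enumeration, filtering and scoring of heterogeneous paths between gene
pairs.

A *path* is a simple walk (no repeated node) between the two genes of a
pair, at most ``path_cutoff`` edges long, whose intermediate nodes avoid a
configurable set of node types (by default Disease and OligogenicCombination,
which inherently contain the answer to the prediction problem).  Traversal
ignores edge direction, but the direction actually travelled is encoded in
the path's *metapath* — its abstract type signature.  Each path gets a
reliability score: the geometric mean of its edge confidence scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .graph import Edge, KnowledgeGraph, Node
from .schema import ABBREV_NODE_TYPE, METAEDGES, NODE_TYPE_ABBREV, SchemaError

__all__ = [
    "MetapathStep",
    "Metapath",
    "PathInstance",
    "GenePairPathIndex",
    "order_pair",
    "enumerate_paths",
    "tissue_consistent",
    "path_reliability",
    "DEFAULT_EXCLUDED_NODE_TYPES",
]

DEFAULT_EXCLUDED_NODE_TYPES = frozenset({"Disease", "OligogenicCombination"})


@dataclass(frozen=True)
class MetapathStep:
    """One typed hop: a metaedge plus the direction it was travelled in.

    For undirected metaedges ``forward`` is canonically True.
    """

    metaedge: str
    forward: bool = True

    def __post_init__(self) -> None:
        meta = METAEDGES[self.metaedge]
        if not meta.directed and not self.forward:
            object.__setattr__(self, "forward", True)

    def next_type(self, current_type: str) -> str:
        meta = METAEDGES[self.metaedge]
        if not meta.directed:
            # undirected metaedges connect nodes of a single type
            return meta.target_type if current_type == meta.source_type \
                else meta.source_type
        return meta.target_type if self.forward else meta.source_type


@dataclass(frozen=True)
class Metapath:
    """Type signature of a path: a sequence of typed, directed steps
    starting and ending at Gene."""

    steps: Tuple[MetapathStep, ...]

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def node_types(self) -> Tuple[str, ...]:
        types = ["Gene"]
        for step in self.steps:
            types.append(step.next_type(types[-1]))
        return tuple(types)

    @property
    def abbreviation(self) -> str:
        """Compact rendering, e.g. ``GaBPaG`` or ``GpGaBPaG``."""
        out = ["G"]
        current = "Gene"
        for step in self.steps:
            meta = METAEDGES[step.metaedge]
            nxt = step.next_type(current)
            out.append(meta.relation_letter)
            out.append(NODE_TYPE_ABBREV[nxt])
            current = nxt
        return "".join(out)

    def __str__(self) -> str:
        return self.abbreviation

    def sort_key(self) -> Tuple:
        return (self.abbreviation, tuple(s.forward for s in self.steps))


@dataclass(frozen=True)
class PathInstance:
    """A concrete walk between a gene pair, with its metapath and score."""

    node_uris: Tuple[str, ...]
    edges: Tuple[Edge, ...]
    metapath: Metapath
    reliability: float


@dataclass
class GenePairPathIndex:
    """All admissible paths of one (ordered) gene pair, grouped by metapath."""

    pair: Tuple[str, str]
    by_metapath: Dict[Metapath, List[PathInstance]] = field(default_factory=dict)

    @property
    def metapaths(self) -> Set[Metapath]:
        return set(self.by_metapath)

    @property
    def n_paths(self) -> int:
        return sum(len(v) for v in self.by_metapath.values())

    def paths(self, metapath: Metapath) -> List[PathInstance]:
        return self.by_metapath.get(metapath, [])


def order_pair(gene_a: Node, gene_b: Node) -> Tuple[Node, Node]:
    """Order a gene pair: lowest RVIS first.

    A gene with a missing RVIS sorts after one with a value; exact ties are
    broken by lexicographic URI, so ordering is deterministic.
    """
    for g in (gene_a, gene_b):
        if g.node_type != "Gene":
            raise TypeError(f"order_pair expects Gene nodes, got {g.node_type}")

    def key(g: Node):
        rvis = g.props.get("RVIS")
        return (rvis is None, rvis if rvis is not None else 0.0, g.uri)

    return tuple(sorted((gene_a, gene_b), key=key))  # type: ignore[return-value]


def path_reliability(edges: Sequence[Edge]) -> float:
    """Geometric mean of edge scores; unscored edges contribute 1.0."""
    if not edges:
        raise ValueError("a path must have at least one edge")
    log_sum = 0.0
    for e in edges:
        s = 1.0 if e.score is None else e.score
        if s <= 0.0:
            return 0.0
        log_sum += math.log(s)
    return math.exp(log_sum / len(edges))


def tissue_consistent(edges: Sequence[Edge]) -> bool:
    """True unless the path crosses ≥2 co-expression edges with disjoint
    tissue sets.  Edges lacking an "in" property count as tissue-universal."""
    tissue_sets = [
        e.tissues for e in edges if e.metaedge == "GeG" and e.tissues is not None
    ]
    n_geg = sum(1 for e in edges if e.metaedge == "GeG")
    if n_geg <= 1 or len(tissue_sets) <= 1:
        return True
    inter = set(tissue_sets[0])
    for ts in tissue_sets[1:]:
        inter &= ts
    return bool(inter)


def enumerate_paths(
    kg: KnowledgeGraph,
    pair: Tuple[str, str],
    path_cutoff: int = 3,
    excluded_node_types: Iterable[str] = DEFAULT_EXCLUDED_NODE_TYPES,
    allowed_metaedges: Optional[Iterable[str]] = None,
) -> GenePairPathIndex:
    """Collect every admissible simple path between an ordered gene pair.

    Parameters
    ----------
    pair:
        (source uri, target uri); traversal starts at the source (the gene
        with the lowest RVIS when ordered with :func:`order_pair`).
    path_cutoff:
        maximum number of edges per path (default 3).
    excluded_node_types:
        intermediate nodes of these types are never traversed.
    allowed_metaedges:
        optional whitelist of metaedge abbreviations (used for
        component-wise connectivity analyses).
    """
    source, target = pair
    for uri in pair:
        if uri not in kg.nodes:
            raise KeyError(f"gene {uri!r} not in graph")
    if path_cutoff < 1:
        raise ValueError("path_cutoff must be >= 1")
    excluded = set(excluded_node_types)
    allowed = None if allowed_metaedges is None else set(allowed_metaedges)

    index = GenePairPathIndex(pair=pair)
    node_stack: List[str] = [source]
    edge_stack: List[Edge] = []
    step_stack: List[MetapathStep] = []
    visited: Set[str] = {source}

    def record() -> None:
        edges = tuple(edge_stack)
        if not tissue_consistent(edges):
            return
        mp = Metapath(tuple(step_stack))
        path = PathInstance(
            node_uris=tuple(node_stack),
            edges=edges,
            metapath=mp,
            reliability=path_reliability(edges),
        )
        index.by_metapath.setdefault(mp, []).append(path)

    def dfs(current: str) -> None:
        for edge, other, fwd in kg.adjacency(current):
            if allowed is not None and edge.metaedge not in allowed:
                continue
            if other in visited:
                continue
            if other == target:
                node_stack.append(other)
                edge_stack.append(edge)
                step_stack.append(MetapathStep(edge.metaedge, fwd))
                record()
                node_stack.pop(); edge_stack.pop(); step_stack.pop()
                continue
            if len(edge_stack) + 1 >= path_cutoff:
                continue
            if kg.nodes[other].node_type in excluded:
                continue
            visited.add(other)
            node_stack.append(other)
            edge_stack.append(edge)
            step_stack.append(MetapathStep(edge.metaedge, fwd))
            dfs(other)
            visited.discard(other)
            node_stack.pop(); edge_stack.pop(); step_stack.pop()

    dfs(source)
    # deterministic path order within each metapath
    for mp in index.by_metapath:
        index.by_metapath[mp].sort(key=lambda p: p.node_uris)
    return index
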
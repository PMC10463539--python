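"""Knowledge-based explanations: translate a matched rule into the exact
subgraph of paths that satisfy it, with per-edge provenance, and export the
result as GraphML for external exploration (e.g. in Cytoscape).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .decision_set import DecisionSetModel
from .graph import Edge, KnowledgeGraph, Node, save_graphml
from .paths import GenePairPathIndex, PathInstance
from .rules import Rule, qualifying_paths

__all__ = ["ExplanationSubgraph", "query_rule", "build_explanation",
           "export_graphml", "explain_pair"]


@dataclass
class ExplanationSubgraph:
    """Union of the explaining paths' nodes and edges.

    ``provenance`` maps each edge key to the (rule id, condition index)
    pairs whose paths use it; ``path_counts`` gives the number of
    qualifying paths per condition.
    """

    nodes: Set[str] = field(default_factory=set)
    edges: Dict[Tuple[str, str, str], Edge] = field(default_factory=dict)
    provenance: Dict[Tuple[str, str, str], Set[Tuple[str, int]]] = field(
        default_factory=dict)
    path_counts: Dict[int, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_paths(self) -> int:
        return sum(self.path_counts.values())


def query_rule(rule: Rule, index: GenePairPathIndex
               ) -> Dict[int, List[PathInstance]]:
    """All paths satisfying each condition of a matching rule.

    For unified rules only the paths through a consistent shared node are
    returned (union over all joint assignments).  Raises if the rule does
    not match the pair.
    """
    qp = qualifying_paths(rule, index)
    if qp is None:
        raise ValueError(
            f"rule {rule.to_text()!r} does not match pair {index.pair}")
    return qp


def build_explanation(paths_per_condition: Dict[int, List[PathInstance]],
                      rule_id: str = "rule0") -> ExplanationSubgraph:
    """Union the returned paths into a provenance-annotated subgraph."""
    sub = ExplanationSubgraph()
    for ci, paths in sorted(paths_per_condition.items()):
        sub.path_counts[ci] = len(paths)
        for p in paths:
            sub.nodes.update(p.node_uris)
            for e in p.edges:
                sub.edges[e.key()] = e
                sub.provenance.setdefault(e.key(), set()).add((rule_id, ci))
    return sub


def export_graphml(subgraph: ExplanationSubgraph, kg: KnowledgeGraph,
                   path) -> None:
    """Write the subgraph as GraphML with node types, edge scores and a
    pipe-joined provenance attribute; the file reloads with the standard
    graph reader."""
    out = KnowledgeGraph()
    for uri in sorted(subgraph.nodes):
        out.add_node(kg.nodes[uri])
    for key, e in sorted(subgraph.edges.items()):
        prov = "|".join(
            f"{rid}:{ci}" for rid, ci in sorted(subgraph.provenance[key]))
        out.add_edge(Edge(e.source, e.target, e.metaedge, e.score, e.tissues,
                          tuple(sorted((*e.properties,
                                        ("provenance", prov))))))
    save_graphml(out, path)


def explain_pair(
    model: DecisionSetModel,
    index: GenePairPathIndex,
) -> Tuple[float, List[Tuple[Rule, ExplanationSubgraph]]]:
    """Predict a pair and build one explanation subgraph per matched rule,
    ranked by rule probability (highest first)."""
    prob, matched = model.predict(index)
    out = []
    for ri, rule in enumerate(matched):
        qp = query_rule(rule, index)
        out.append((rule, build_explanation(qp, rule_id=f"rule{ri}")))
    return prob, out
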
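"""Edge-scoring and filtering formulas used when assembling a
schema-conformant knowledge graph from tabular sources.

Covers: functional information of ontology annotation terms, SimGIC
semantic similarity between terms, the BLAST score ratio for sequence
similarity edges, co-expression record filtering, and collapsing
protein-level edges onto genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx
from scipy.stats import norm

from .graph import Edge

__all__ = [
    "OntologyHierarchy",
    "CoexpressionRecord",
    "functional_information",
    "simgic",
    "blast_score_ratio",
    "filter_coexpression",
    "collapse_to_genes",
    "phenotype_frequency_score",
    "SIMGIC_EDGE_MIN",
    "BSR_EDGE_MIN",
]

#: a "resembles" edge is emitted only above this SimGIC value
SIMGIC_EDGE_MIN = 0.5
#: a "seqsimilar" edge is emitted only at or above this BSR value
BSR_EDGE_MIN = 0.2


@dataclass
class OntologyHierarchy:
    """An is-a DAG of terms with per-term gene annotations."""

    terms: Set[str]
    is_a: Dict[str, Set[str]]  # child -> parents
    annotations: Dict[str, Set[str]]  # term -> annotated genes

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parents in self.is_a.items():
            for p in parents:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a relation must be acyclic")
        for t in self.annotations:
            if t not in self.terms:
                raise ValueError(f"annotated term {t!r} not in hierarchy")
        self._dag = g

    def ancestors(self, term: str) -> Set[str]:
        """Ancestors of ``term``, inclusive of the term itself."""
        if term not in self.terms:
            raise KeyError(term)
        return {term} | nx.descendants(self._dag, term)  # edges point child->parent

    def subterms(self, term: str) -> Set[str]:
        """Descendants of ``term``, inclusive."""
        if term not in self.terms:
            raise KeyError(term)
        return {term} | nx.ancestors(self._dag, term)

    def all_annotated_genes(self) -> Set[str]:
        out: Set[str] = set()
        for genes in self.annotations.values():
            out |= genes
        return out


def functional_information(term: str, hierarchy: OntologyHierarchy) -> float:
    """Rarity-based informativeness of an annotation term in [0, 1].

    FI(t) = -log(|g(t and subterms)| / |g(T)|) / log(|g(T)|): 0 for a term
    annotating every gene of the ontology, 1 for a term annotating a single
    gene.  Uses the natural logarithm; the base cancels in the ratio.
    """
    universe = hierarchy.all_annotated_genes()
    if not universe:
        raise ValueError("ontology annotates no genes")
    genes: Set[str] = set()
    for t in hierarchy.subterms(term):
        genes |= hierarchy.annotations.get(t, set())
    if not genes:
        raise ValueError(f"term {term!r} annotates no genes; FI undefined")
    n_universe = len(universe)
    if n_universe < 2:
        raise ValueError("FI undefined for a single-gene universe")
    return -math.log(len(genes) / n_universe) / math.log(n_universe)


def simgic(term_a: str, term_b: str, hierarchy: OntologyHierarchy,
           ic: Mapping[str, float]) -> float:
    """Graph-information-content similarity: IC sum over shared ancestors
    (terms included) divided by the IC sum over the ancestor union."""
    anc_a = hierarchy.ancestors(term_a)
    anc_b = hierarchy.ancestors(term_b)
    inter = sum(ic.get(t, 0.0) for t in anc_a & anc_b)
    union = sum(ic.get(t, 0.0) for t in anc_a | anc_b)
    if union <= 0:
        raise ValueError("ancestor-union information content is zero")
    return inter / union


def blast_score_ratio(bitscore_ab: float, self_a: float, self_b: float,
                      coverage_fraction: float) -> Optional[float]:
    """BSR in [0, 1], or None when the alignment covers < 50% of the
    shorter protein.  The cross bit score is normalised by the smaller of
    the two self-alignment scores and clamped at 1."""
    if self_a <= 0 or self_b <= 0:
        raise ValueError("self-alignment scores must be positive")
    if coverage_fraction < 0.5:
        return None
    return min(1.0, bitscore_ab / min(self_a, self_b))


@dataclass(frozen=True)
class CoexpressionRecord:
    gene_a: str
    gene_b: str
    tissue: str
    rho: float
    adj_p: float
    n_samples: int
    z_a: float = 0.0
    z_b: float = 0.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [-1, 1]")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")


def _fisher_rho_gate(rho: float, n: int, min_rho: float, alpha: float) -> bool:
    """Sample-size-adjusted correlation gate: accept when the Fisher
    z-transformed correlation reaches atanh(min_rho) minus an alpha-level
    one-sided margin of 1/sqrt(n - 3)."""
    if n <= 3:
        return rho >= min_rho
    z_crit = norm.ppf(1.0 - alpha)
    return math.atanh(min(rho, 1 - 1e-12)) >= (
        math.atanh(min_rho) - z_crit / math.sqrt(n - 3)
    )


def filter_coexpression(
    records: Iterable[CoexpressionRecord],
    min_rho: float = 0.80,
    max_adj_p: float = 0.01,
    min_samples: int = 70,
    min_z: float = -3.0,
    fisher_alpha: float = 0.01,
) -> List[Edge]:
    """Filter tissue co-expression records and group survivors per gene
    pair into GeG edges scored by the maximum correlation across tissues,
    with the surviving tissues in the "in" property."""
    surviving: Dict[Tuple[str, str], List[CoexpressionRecord]] = {}
    for r in records:
        if r.n_samples < min_samples:
            continue
        if r.z_a < min_z or r.z_b < min_z:
            continue
        if not (r.adj_p < max_adj_p):
            continue
        if not _fisher_rho_gate(r.rho, r.n_samples, min_rho, fisher_alpha):
            continue
        pair = tuple(sorted((r.gene_a, r.gene_b)))
        surviving.setdefault(pair, []).append(r)
    edges = []
    for (a, b), recs in sorted(surviving.items()):
        edges.append(
            Edge(a, b, "GeG", score=max(r.rho for r in recs),
                 tissues=frozenset(r.tissue for r in recs))
        )
    return edges


def collapse_to_genes(
    protein_edges: Iterable[Tuple[str, str, str, Optional[float]]],
    protein_to_gene: Mapping[str, str],
) -> Tuple[List[Edge], Dict[str, int]]:
    """Collapse protein-level edges (prot_a, prot_b, metaedge, score) onto
    their genes: one edge per (gene pair, metaedge) with the maximum score;
    within-gene self edges are dropped; edges with an unmapped protein are
    skipped and counted in the report."""
    best: Dict[Tuple[str, str, str], Optional[float]] = {}
    report = {"collapsed": 0, "self_edges_dropped": 0, "unmapped_skipped": 0}
    for pa, pb, metaedge, score in protein_edges:
        ga = protein_to_gene.get(pa)
        gb = protein_to_gene.get(pb)
        if ga is None or gb is None:
            report["unmapped_skipped"] += 1
            continue
        if ga == gb:
            report["self_edges_dropped"] += 1
            continue
        a, b = sorted((ga, gb))
        key = (a, b, metaedge)
        if key in best:
            prev = best[key]
            if score is not None and (prev is None or score > prev):
                best[key] = score
        else:
            best[key] = score
            report["collapsed"] += 1
    return (
        [Edge(a, b, m, score=s) for (a, b, m), s in sorted(best.items())],
        report,
    )


#: HPO-style phenotype frequency classes mapped to the midpoint of their
#: frequency range (fraction of patients presenting the phenotype).
_FREQUENCY_CLASS_SCORE = {
    "obligate": 1.0,  # 100%
    "very frequent": (0.80 + 0.99) / 2,
    "frequent": (0.30 + 0.79) / 2,
    "occasional": (0.05 + 0.29) / 2,
    "very rare": (0.01 + 0.04) / 2,
    "excluded": 0.0,  # 0%
}


def phenotype_frequency_score(frequency_class: Optional[str]) -> Optional[float]:
    """Score for a Disease-described-Phenotype edge from its categorical
    frequency class; None when the class is missing or unknown."""
    if frequency_class is None:
        return None
    return _FREQUENCY_CLASS_SCORE.get(frequency_class.strip().lower())
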
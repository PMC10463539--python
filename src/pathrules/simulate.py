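"""Synthetic schema-conformant knowledge graphs with planted metapath
patterns.

The generator emulates the study's inputs at desk scale: a typed graph with
background edges per metaedge (Erdos-Renyi-style endpoint sampling, Beta
distributed confidence scores), genes carrying RVIS values, and two labelled
gene-pair sets.  Each *planted pattern* — a set of metapaths, optionally
with a unification constraint — is wired into a positive pair with
probability ``p_pos`` and into a negative pair with probability ``p_neg``,
so mining and training can be checked against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import Edge, KnowledgeGraph, Node
from .paths import Metapath, MetapathStep, enumerate_paths, order_pair
from .rules import Rule, UnificationConstraint, rule_from_itemset
from .schema import METAEDGES

__all__ = ["PlantedPattern", "SimulationConfig", "SyntheticData",
           "generate", "plant_pattern", "metapath"]

_TISSUES = ("heart", "liver", "brain", "kidney", "muscle")


def metapath(steps: Sequence[Tuple[str, bool]]) -> Metapath:
    """Build a metapath from (metaedge abbreviation, forward) pairs."""
    return Metapath(tuple(MetapathStep(m, f) for m, f in steps))


#: canonical shapes used by the default planted patterns
MP_GaBPaG = metapath([("GaBP", True), ("GaBP", False)])
MP_GpG = metapath([("GpG", True)])
MP_GaMFaG = metapath([("GaMF", True), ("GaMF", False)])
MP_GaBPaGpG = metapath([("GaBP", True), ("GaBP", False), ("GpG", True)])


@dataclass(frozen=True)
class PlantedPattern:
    """Ground-truth pattern: metapaths planted jointly into a pair."""

    metapaths: Tuple[Metapath, ...]
    unification: Optional[UnificationConstraint] = None
    reliability_range: Tuple[float, float] = (0.7, 1.0)

    def to_rule(self) -> Rule:
        return rule_from_itemset(self.metapaths, unification=self.unification)


def _default_patterns() -> Tuple[PlantedPattern, ...]:
    return (
        PlantedPattern((MP_GaBPaG,)),
        PlantedPattern((MP_GpG, MP_GaMFaG)),
        PlantedPattern(
            (MP_GaBPaG, MP_GaBPaGpG),
            # shared BiologicalProcess at position 1 of both (sorted) conditions
            unification=UnificationConstraint(0, 1, 1, 1, "BiologicalProcess"),
        ),
    )


def _default_edge_counts() -> Dict[str, int]:
    return {
        "GpG": 300, "GeG": 200, "GsG": 100,
        "GaBP": 350, "GaMF": 180, "GaCC": 120, "GaP": 150,
        "GbPF": 80, "GuPD": 80, "GfPC": 60,
        "BPrBP": 60, "MFrMF": 30, "CCrCC": 15, "PrP": 30,
        "DdP": 30, "OCiG": 24, "OCcD": 12,
    }


def _default_type_counts() -> Dict[str, int]:
    return {
        "BiologicalProcess": 60, "MolecularFunction": 40,
        "CellularComponent": 30, "Phenotype": 40, "ProteinDomain": 30,
        "ProteinFamily": 30, "ProteinComplex": 20, "Disease": 10,
        "OligogenicCombination": 12,
    }


@dataclass
class SimulationConfig:
    n_genes: int = 300
    edge_counts: Dict[str, int] = field(default_factory=_default_edge_counts)
    type_counts: Dict[str, int] = field(default_factory=_default_type_counts)
    planted_patterns: Tuple[PlantedPattern, ...] = field(
        default_factory=_default_patterns)
    n_positive_pairs: int = 60
    n_negative_pairs: int = 600
    p_pos: float = 0.9
    p_neg: float = 0.02
    score_beta: Tuple[float, float] = (4.0, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_neg < self.p_pos <= 1.0):
            raise ValueError("require 0 <= p_neg < p_pos <= 1")
        if self.n_genes < 4:
            raise ValueError("need at least 4 genes")
        for m, c in self.edge_counts.items():
            if m not in METAEDGES or c < 0:
                raise ValueError(f"bad edge count for {m!r}")


@dataclass
class SyntheticData:
    kg: KnowledgeGraph
    positive_pairs: List[Tuple[str, str, float]]  # (source, target, weight)
    negative_pairs: List[Tuple[str, str, float]]
    true_rules: List[Rule]
    config: SimulationConfig


def _type_prefix(node_type: str) -> str:
    return "".join(c for c in node_type if c.isupper()).lower()


def generate(config: Optional[SimulationConfig] = None,
             seed: Optional[int] = None) -> SyntheticData:
    """Generate a knowledge graph plus labelled gene pairs and ground truth.

    Fully reproducible: the same config and seed yield an identical graph,
    pair sets and planted rules.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    config.validate()
    rng = np.random.default_rng(config.seed)
    kg = KnowledgeGraph()

    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    rvis = rng.standard_normal(config.n_genes)
    for g, r in zip(genes, rvis):
        kg.add_node(Node(g, "Gene", (("RVIS", float(r)),)))
    by_type: Dict[str, List[str]] = {"Gene": genes}
    for node_type, count in sorted(config.type_counts.items()):
        prefix = _type_prefix(node_type)
        uris = [f"{prefix}{i:04d}" for i in range(count)]
        for u in uris:
            kg.add_node(Node(u, node_type))
        by_type[node_type] = uris

    # background edges
    for abbrev in sorted(config.edge_counts):
        meta = METAEDGES[abbrev]
        n = config.edge_counts[abbrev]
        src_pool = by_type.get(meta.source_type, [])
        tgt_pool = by_type.get(meta.target_type, [])
        if not src_pool or not tgt_pool:
            continue
        made = 0
        while made < n:
            s = src_pool[rng.integers(len(src_pool))]
            t = tgt_pool[rng.integers(len(tgt_pool))]
            if s == t:
                continue
            score = float(rng.beta(*config.score_beta))
            tissues = None
            if abbrev == "GeG":
                k = int(rng.integers(1, 4))
                tissues = frozenset(
                    rng.choice(_TISSUES, size=k, replace=False).tolist())
            kg.add_edge(Edge(s, t, abbrev, score=score, tissues=tissues))
            made += 1

    # labelled pairs (disjoint unordered pairs)
    n_pairs = config.n_positive_pairs + config.n_negative_pairs
    seen = set()
    pairs: List[Tuple[str, str]] = []
    while len(pairs) < n_pairs:
        i, j = rng.integers(config.n_genes), rng.integers(config.n_genes)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((genes[key[0]], genes[key[1]]))
    def ordered(pair: Tuple[str, str]) -> Tuple[str, str]:
        a, b = order_pair(kg.nodes[pair[0]], kg.nodes[pair[1]])
        return a.uri, b.uri

    # patterns are planted on the RVIS-ordered pair: metapaths are read
    # from the low-RVIS source gene, and direction is part of their identity
    pos_raw = [ordered(p) for p in pairs[: config.n_positive_pairs]]
    neg_raw = [ordered(p) for p in pairs[config.n_positive_pairs:]]

    for pair in pos_raw:
        for pattern in config.planted_patterns:
            if rng.random() < config.p_pos:
                plant_pattern(kg, pair, pattern, rng, by_type)
    for pair in neg_raw:
        for pattern in config.planted_patterns:
            if rng.random() < config.p_neg:
                plant_pattern(kg, pair, pattern, rng, by_type)

    level_weights = (0.25, 0.5, 1.0)
    positive = [
        (*p, level_weights[rng.choice(3, p=(0.2, 0.3, 0.5))])
        for p in pos_raw
    ]
    negative = [
        (*p, float(rng.uniform(0.5, 1.0))) for p in neg_raw
    ]
    return SyntheticData(
        kg=kg,
        positive_pairs=positive,
        negative_pairs=negative,
        true_rules=[p.to_rule() for p in config.planted_patterns],
        config=config,
    )


def plant_pattern(
    kg: KnowledgeGraph,
    pair: Tuple[str, str],
    pattern: PlantedPattern,
    rng: np.random.Generator,
    by_type: Optional[Dict[str, List[str]]] = None,
) -> KnowledgeGraph:
    """Wire concrete paths realizing ``pattern`` between ``pair``.

    Intermediate nodes are drawn from the existing nodes of the required
    type (distinct within each path and from the pair); a unification
    constraint re-uses one shared node across its two conditions.  Edge
    scores are drawn uniformly from the pattern's reliability range, so
    every planted path's geometric-mean reliability is at least the range's
    lower bound.
    """
    for g in pair:
        if g not in kg.nodes:
            raise KeyError(f"gene {g!r} not in graph")
    if by_type is None:
        by_type = {}
        for node in kg.nodes.values():
            by_type.setdefault(node.node_type, []).append(node.uri)

    mps = sorted(set(pattern.metapaths), key=Metapath.sort_key)
    lo, hi = pattern.reliability_range
    u = pattern.unification
    shared_node: Optional[str] = None
    if u is not None:
        pool = [x for x in by_type.get(u.node_type, []) if x not in pair]
        if not pool:
            raise ValueError(f"no {u.node_type} nodes available to unify on")
        shared_node = pool[rng.integers(len(pool))]

    for mi, mp in enumerate(mps):
        types = mp.node_types
        nodes: List[Optional[str]] = [None] * len(types)
        nodes[0], nodes[-1] = pair
        if u is not None and mi == u.i:
            nodes[u.position_i] = shared_node
        if u is not None and mi == u.j:
            nodes[u.position_j] = shared_node
        for pos in range(1, len(types) - 1):
            if nodes[pos] is not None:
                continue
            pool = [
                x for x in by_type.get(types[pos], [])
                if x not in pair and x not in nodes
            ]
            if not pool:
                raise ValueError(
                    f"no {types[pos]} nodes available for planting")
            nodes[pos] = pool[rng.integers(len(pool))]
        for si, step in enumerate(mp.steps):
            a, b = nodes[si], nodes[si + 1]
            meta = METAEDGES[step.metaedge]
            if meta.directed and not step.forward:
                a, b = b, a
            score = float(rng.uniform(lo, hi))
            tissues = frozenset(_TISSUES) if step.metaedge == "GeG" else None
            kg.add_edge(Edge(a, b, step.metaedge, score=score,
                             tissues=tissues))
    return kg
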
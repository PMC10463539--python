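"""Shared fixtures: hand-built graphs, synthetic path indexes, and random
schema-conformant graph generation for oracle-equivalence tests."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from pathrules.graph import Edge, KnowledgeGraph, Node
from pathrules.paths import GenePairPathIndex, Metapath, PathInstance
from pathrules.rules import Transaction
from pathrules.schema import METAEDGES
from pathrules.simulate import metapath


# ---------------------------------------------------------------------
# Hand-built graphs
# ---------------------------------------------------------------------

@pytest.fixture
def tiny_kg() -> KnowledgeGraph:
    """3 genes, 2 physical interactions, one co-expression with tissues."""
    kg = KnowledgeGraph()
    kg.add_node(Node("gA", "Gene", (("RVIS", -1.2),)))
    kg.add_node(Node("gB", "Gene", (("RVIS", 0.4),)))
    kg.add_node(Node("gC", "Gene"))
    kg.add_edge(Edge("gA", "gB", "GpG", score=0.9))
    kg.add_edge(Edge("gB", "gC", "GpG", score=0.8))
    kg.add_edge(Edge("gA", "gC", "GeG", score=0.85,
                     tissues=frozenset({"liver", "heart"})))
    return kg


# ---------------------------------------------------------------------
# Synthetic path indexes (no graph needed)
# ---------------------------------------------------------------------

def make_index(
    pair: Tuple[str, str],
    paths: Dict[Metapath, Sequence[Tuple[float, Tuple[str, ...]]]],
) -> GenePairPathIndex:
    """Build a path index from (reliability, node sequence) stubs.

    Edges are synthesized with uniform scores reproducing the requested
    reliability, so reliability-threshold logic behaves as on real paths.
    """
    index = GenePairPathIndex(pair=pair)
    for mp, specs in paths.items():
        insts = []
        for rel, nodes in specs:
            assert len(nodes) == mp.length + 1
            edges = []
            for si, step in enumerate(mp.steps):
                meta = METAEDGES[step.metaedge]
                a, b = nodes[si], nodes[si + 1]
                if meta.directed and not step.forward:
                    a, b = b, a
                edges.append(Edge(a, b, step.metaedge, score=rel))
            insts.append(PathInstance(tuple(nodes), tuple(edges), mp, rel))
        index.by_metapath[mp] = list(insts)
    return index


def make_transactions(
    specs: Sequence[Tuple[float, Dict[Metapath, Sequence]]],
) -> List[Transaction]:
    out = []
    for i, (weight, paths) in enumerate(specs):
        idx = make_index((f"s{i}", f"t{i}"), paths)
        out.append(Transaction.from_index(f"pair{i}", weight, idx))
    return out


# common metapaths for rule tests
MP_GpG = metapath([("GpG", True)])
MP_GaBPaG = metapath([("GaBP", True), ("GaBP", False)])
MP_GaMFaG = metapath([("GaMF", True), ("GaMF", False)])
MP_GaBPaGpG = metapath([("GaBP", True), ("GaBP", False), ("GpG", True)])


# ---------------------------------------------------------------------
# Random schema-conformant graphs for path-oracle tests
# ---------------------------------------------------------------------

def random_kg(rng: np.random.Generator, n_genes: int = 8, n_bp: int = 4,
              n_mf: int = 3, n_pheno: int = 3, n_edges: int = 40
              ) -> KnowledgeGraph:
    kg = KnowledgeGraph()
    genes = [f"g{i}" for i in range(n_genes)]
    bps = [f"bp{i}" for i in range(n_bp)]
    mfs = [f"mf{i}" for i in range(n_mf)]
    phenos = [f"ph{i}" for i in range(n_pheno)]
    for g in genes:
        kg.add_node(Node(g, "Gene", (("RVIS", float(rng.standard_normal())),)))
    for u in bps:
        kg.add_node(Node(u, "BiologicalProcess"))
    for u in mfs:
        kg.add_node(Node(u, "MolecularFunction"))
    for u in phenos:
        kg.add_node(Node(u, "Phenotype"))
    pools = {
        "GpG": (genes, genes), "GeG": (genes, genes), "GsG": (genes, genes),
        "GaBP": (genes, bps), "GaMF": (genes, mfs), "GaP": (genes, phenos),
        "BPrBP": (bps, bps), "PrP": (phenos, phenos),
    }
    tissues = ["heart", "liver", "brain"]
    metaedges = sorted(pools)
    for _ in range(n_edges):
        m = metaedges[rng.integers(len(metaedges))]
        src_pool, tgt_pool = pools[m]
        s = src_pool[rng.integers(len(src_pool))]
        t = tgt_pool[rng.integers(len(tgt_pool))]
        if s == t:
            continue
        tset = None
        if m == "GeG":
            k = int(rng.integers(1, 3))
            tset = frozenset(
                rng.choice(tissues, size=k, replace=False).tolist())
        kg.add_edge(Edge(s, t, m, score=float(rng.uniform(0.05, 1.0)),
                         tissues=tset))
    return kg


# ---------------------------------------------------------------------
# Independent brute-force path oracle
# ---------------------------------------------------------------------

def oracle_paths(kg: KnowledgeGraph, source: str, target: str, cutoff: int,
                 excluded_types: frozenset,
                 ) -> set:
    """Exhaustive simple-path enumeration working directly on the edge
    list, independent of the adjacency-based engine.  Returns signatures
    (node tuple, metaedge tuple, direction tuple)."""
    import math

    edges = kg.edges
    results = set()

    def extend(nodes: Tuple[str, ...], used: Tuple, dirs: Tuple):
        current = nodes[-1]
        if current == target and used:
            # tissue consistency
            tsets = [e.tissues for e in used
                     if e.metaedge == "GeG" and e.tissues is not None]
            ok = True
            if sum(1 for e in used if e.metaedge == "GeG") > 1 and \
                    len(tsets) > 1:
                inter = set(tsets[0])
                for ts in tsets[1:]:
                    inter &= ts
                ok = bool(inter)
            if ok:
                results.add((
                    nodes,
                    tuple(e.metaedge for e in used),
                    dirs,
                ))
            return
        if len(used) >= cutoff:
            return
        if used and kg.nodes[current].node_type in excluded_types:
            return
        for e in edges:
            for s, t, fwd in ((e.source, e.target, True),
                              (e.target, e.source, False)):
                if s != current or t in nodes[:-1] or t == current:
                    continue
                if t in nodes:
                    continue
                extend(nodes + (t,), used + (e,),
                       dirs + (fwd or not e.meta.directed,))
        return

    extend((source,), (), ())
    return results
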
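"""Typed schema of the oligogenic knowledge graph.

The graph has 10 node types (metanodes) and 17 edge types (metaedges).
Every metaedge is uniquely identified by its (source type, relation,
target type) triple and carries a compact abbreviation built from the two
metanode abbreviations with the relation's single lower-case letter in
between (e.g. ``GaBP`` = Gene -associated-> BiologicalProcess).  Seven
metaedges are undirected associations; the rest are directed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = [
    "NodeType",
    "Metaedge",
    "NODE_TYPES",
    "NODE_TYPE_ABBREV",
    "ABBREV_NODE_TYPE",
    "METAEDGES",
    "metaedge_by_abbrev",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised when a graph element does not conform to the schema."""


#: metanode name -> abbreviation
NODE_TYPE_ABBREV: Dict[str, str] = {
    "Gene": "G",
    "Disease": "D",
    "Phenotype": "P",
    "BiologicalProcess": "BP",
    "MolecularFunction": "MF",
    "CellularComponent": "CC",
    "ProteinDomain": "PD",
    "ProteinFamily": "PF",
    "ProteinComplex": "PC",
    "OligogenicCombination": "OC",
}

ABBREV_NODE_TYPE: Dict[str, str] = {v: k for k, v in NODE_TYPE_ABBREV.items()}

NODE_TYPES: Tuple[str, ...] = tuple(NODE_TYPE_ABBREV)


@dataclass(frozen=True)
class NodeType:
    """A metanode: a named node type with its abbreviation."""

    name: str
    abbreviation: str

    def __post_init__(self) -> None:
        if self.name not in NODE_TYPE_ABBREV:
            raise SchemaError(f"unknown node type: {self.name!r}")


@dataclass(frozen=True)
class Metaedge:
    """A metaedge: a typed, optionally directed relation between metanodes."""

    source_type: str
    relation: str
    target_type: str
    directed: bool
    abbreviation: str

    def __post_init__(self) -> None:
        for t in (self.source_type, self.target_type):
            if t not in NODE_TYPE_ABBREV:
                raise SchemaError(f"unknown node type: {t!r}")

    @property
    def relation_letter(self) -> str:
        """Lower-case run inside the abbreviation (e.g. 'a' of GaBP)."""
        return "".join(c for c in self.abbreviation if c.islower())


def _me(src: str, rel: str, tgt: str, directed: bool, abbrev: str) -> Metaedge:
    return Metaedge(src, rel, tgt, directed, abbrev)


#: The 17 metaedges, keyed by abbreviation.
METAEDGES: Dict[str, Metaedge] = {
    m.abbreviation: m
    for m in [
        _me("Gene", "coexpresses", "Gene", False, "GeG"),
        _me("Gene", "physinteracts", "Gene", False, "GpG"),
        _me("Disease", "described", "Phenotype", True, "DdP"),
        _me("Gene", "associated", "Phenotype", True, "GaP"),
        _me("Gene", "seqsimilar", "Gene", False, "GsG"),
        _me("Gene", "associated", "BiologicalProcess", True, "GaBP"),
        _me("Gene", "associated", "CellularComponent", True, "GaCC"),
        _me("Gene", "belongs", "ProteinFamily", True, "GbPF"),
        _me("Gene", "associated", "MolecularFunction", True, "GaMF"),
        _me("Gene", "hasunit", "ProteinDomain", True, "GuPD"),
        _me("BiologicalProcess", "resembles", "BiologicalProcess", False, "BPrBP"),
        _me("Phenotype", "resembles", "Phenotype", False, "PrP"),
        _me("Gene", "forms", "ProteinComplex", True, "GfPC"),
        _me("MolecularFunction", "resembles", "MolecularFunction", False, "MFrMF"),
        _me("OligogenicCombination", "involves", "Gene", True, "OCiG"),
        _me("OligogenicCombination", "causes", "Disease", True, "OCcD"),
        _me("CellularComponent", "resembles", "CellularComponent", False, "CCrCC"),
    ]
}

#: Undirected metaedges, stored once in canonical endpoint order.
UNDIRECTED_METAEDGES = frozenset(a for a, m in METAEDGES.items() if not m.directed)


def metaedge_by_abbrev(abbrev: str) -> Metaedge:
    try:
        return METAEDGES[abbrev]
    except KeyError:
        raise SchemaError(f"unknown metaedge abbreviation: {abbrev!r}") from None
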
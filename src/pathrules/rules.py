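"""Class association rule mining over metapath itemsets.

A *rule* is a conjunction of metapath conditions — "the pair has at least
one path of this metapath with reliability >= theta" — optionally extended
with a single *unification* constraint forcing paths of two different
conditions to pass through the same intermediate node (e.g. BP1 = BP2).
Rules are mined from the positive (disease-causing) pairs only, with a
level-wise Apriori search under weighted minimum support, and reduced to
closed patterns (no strict super-pattern of identical support).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .paths import GenePairPathIndex, Metapath, PathInstance

__all__ = [
    "Transaction",
    "UnificationConstraint",
    "Rule",
    "qualifying_paths",
    "matches",
    "weighted_support",
    "apriori_mine",
    "extend_with_unifications",
    "closed_only",
    "rule_confidence",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Transaction:
    """One labelled gene pair seen by the miner: its metapath itemset, its
    label-confidence weight, and the path index needed for unification and
    threshold tests."""

    pair_id: str
    weight: float
    items: FrozenSet[Metapath]
    index: GenePairPathIndex

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise ValueError("transaction weight must be > 0")

    @classmethod
    def from_index(cls, pair_id: str, weight: float,
                   index: GenePairPathIndex) -> "Transaction":
        return cls(pair_id, weight, frozenset(index.metapaths), index)


@dataclass(frozen=True)
class UnificationConstraint:
    """Force conditions ``i`` and ``j`` to share the node at the given
    intermediate positions (indices into each metapath's node sequence)."""

    i: int
    position_i: int
    j: int
    position_j: int
    node_type: str

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("unification must span two different conditions")


@dataclass(eq=True)
class Rule:
    """Conditions (metapath, reliability threshold) + optional unification.

    ``support``, ``confidence`` and ``probability`` are training statistics
    and do not participate in rule identity.
    """

    conditions: Tuple[Tuple[Metapath, float], ...]
    unification: Optional[UnificationConstraint] = None
    support: float = field(default=math.nan, compare=False)
    confidence: float = field(default=math.nan, compare=False)
    probability: float = field(default=math.nan, compare=False)

    def __post_init__(self) -> None:
        for _, theta in self.conditions:
            if not (0.0 <= theta <= 1.0):
                raise ValueError("reliability thresholds must lie in [0, 1]")

    def __hash__(self) -> int:
        return hash((self.conditions, self.unification))

    @property
    def metapaths(self) -> Tuple[Metapath, ...]:
        return tuple(mp for mp, _ in self.conditions)

    @property
    def items(self) -> FrozenSet[Metapath]:
        return frozenset(self.metapaths)

    @property
    def thetas(self) -> Tuple[float, ...]:
        return tuple(theta for _, theta in self.conditions)

    def with_thetas(self, thetas: Sequence[float]) -> "Rule":
        if len(thetas) != len(self.conditions):
            raise ValueError("one threshold per condition required")
        conds = tuple(
            (mp, float(t)) for (mp, _), t in zip(self.conditions, thetas)
        )
        return replace(self, conditions=conds)

    def to_text(self) -> str:
        """Human-readable form, e.g. ``GaBPaG >= 0.21 & GpG >= 0.00 | BP1=BP2``."""
        parts = [f"{mp.abbreviation} >= {theta:.2f}"
                 for mp, theta in self.conditions]
        text = " & ".join(parts)
        u = self.unification
        if u is not None:
            from .schema import NODE_TYPE_ABBREV

            ab = NODE_TYPE_ABBREV[u.node_type]
            text += f" | {ab}1={ab}2"
        return text

    def sort_key(self) -> Tuple:
        return (
            tuple(mp.sort_key() for mp in self.metapaths),
            self.thetas,
            (self.unification.i, self.unification.position_i,
             self.unification.j, self.unification.position_j)
            if self.unification else (),
        )


def rule_from_itemset(items: Iterable[Metapath],
                      unification: Optional[UnificationConstraint] = None,
                      thetas: Optional[Sequence[float]] = None) -> Rule:
    mps = sorted(set(items), key=Metapath.sort_key)
    if thetas is None:
        thetas = [0.0] * len(mps)
    return Rule(tuple(zip(mps, (float(t) for t in thetas))), unification)


# ---------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------

def qualifying_paths(
    rule: Rule, index: GenePairPathIndex
) -> Optional[Dict[int, List[PathInstance]]]:
    """Paths satisfying each condition, or None if the rule does not match.

    For a unified rule the two constrained conditions are restricted to the
    paths passing through *some* consistent shared node (the union over all
    joint assignments); the other conditions keep every qualifying path.
    """
    per_cond: Dict[int, List[PathInstance]] = {}
    for ci, (mp, theta) in enumerate(rule.conditions):
        paths = [p for p in index.paths(mp) if p.reliability >= theta - _EPS]
        if not paths:
            return None
        per_cond[ci] = paths
    u = rule.unification
    if u is not None:
        nodes_i = {p.node_uris[u.position_i] for p in per_cond[u.i]}
        nodes_j = {p.node_uris[u.position_j] for p in per_cond[u.j]}
        shared = nodes_i & nodes_j
        if not shared:
            return None
        per_cond[u.i] = [p for p in per_cond[u.i]
                         if p.node_uris[u.position_i] in shared]
        per_cond[u.j] = [p for p in per_cond[u.j]
                         if p.node_uris[u.position_j] in shared]
    return per_cond


def matches(rule: Rule, index: GenePairPathIndex) -> bool:
    return qualifying_paths(rule, index) is not None


def weighted_support(rule: Rule, transactions: Sequence[Transaction]) -> float:
    """Sum of covered weights over the total weight of the transaction set."""
    total = sum(t.weight for t in transactions)
    if total <= 0:
        raise ValueError("transactions carry no weight")
    covered = sum(t.weight for t in transactions if matches(rule, t.index))
    return covered / total


# ---------------------------------------------------------------------
# Apriori mining
# ---------------------------------------------------------------------

def apriori_mine(
    transactions: Sequence[Transaction],
    minsup_ratio: float = 0.2,
    max_rule_length: int = 3,
) -> List[Tuple[FrozenSet[Metapath], float]]:
    """Level-wise search for frequent metapath itemsets.

    Support is the weighted fraction of transactions whose itemset contains
    the candidate; the returned list holds every itemset of size
    <= ``max_rule_length`` with support >= ``minsup_ratio``.
    """
    if not transactions:
        raise ValueError("cannot mine an empty transaction set")
    if not (0.0 < minsup_ratio <= 1.0):
        raise ValueError("minsup_ratio must lie in (0, 1]")
    import numpy as np

    weights = np.array([t.weight for t in transactions], dtype=float)
    total = float(weights.sum())

    universe = sorted({mp for t in transactions for mp in t.items},
                      key=Metapath.sort_key)
    item_cov = {
        mp: np.array([mp in t.items for t in transactions], dtype=bool)
        for mp in universe
    }

    frequent: List[Tuple[FrozenSet[Metapath], float]] = []
    current: dict = {}  # frozenset -> coverage array
    for mp in universe:
        cov = item_cov[mp]
        s = float(weights[cov].sum()) / total
        if s >= minsup_ratio - _EPS:
            frequent.append((frozenset([mp]), s))
            current[frozenset([mp])] = cov

    k = 2
    while current and k <= max_rule_length:
        prev = set(current)
        # join step: union pairs differing by one item, then prune
        candidates = set()
        for a, b in combinations(current, 2):
            u = a | b
            if len(u) == k and all(u - {x} in prev for x in u):
                candidates.add(u)
        nxt: dict = {}
        for cand in sorted(candidates,
                           key=lambda s: tuple(sorted(mp.sort_key()
                                                      for mp in s))):
            some = next(iter(cand))
            cov = current[cand - {some}] & item_cov[some]
            s = float(weights[cov].sum()) / total
            if s >= minsup_ratio - _EPS:
                frequent.append((cand, s))
                nxt[cand] = cov
        current = nxt
        k += 1
    return frequent


def unification_candidates(items: Sequence[Metapath]
                           ) -> List[UnificationConstraint]:
    """All single unifications over intermediate positions of equal node
    type across two different conditions (conditions in sorted order)."""
    mps = sorted(set(items), key=Metapath.sort_key)
    out: List[UnificationConstraint] = []
    for i, j in combinations(range(len(mps)), 2):
        types_i = mps[i].node_types
        types_j = mps[j].node_types
        for pi in range(1, len(types_i) - 1):
            for pj in range(1, len(types_j) - 1):
                if types_i[pi] == types_j[pj]:
                    out.append(
                        UnificationConstraint(i, pi, j, pj, types_i[pi])
                    )
    return out


def extend_with_unifications(
    itemsets: Sequence[Tuple[FrozenSet[Metapath], float]],
    transactions: Sequence[Transaction],
    minsup_ratio: float = 0.2,
) -> List[Rule]:
    """Emit unified rules (one constraint each) that stay frequent."""
    out: List[Rule] = []
    for items, _ in itemsets:
        if len(items) < 2:
            continue
        for u in unification_candidates(sorted(items, key=Metapath.sort_key)):
            rule = rule_from_itemset(items, unification=u)
            s = weighted_support(rule, transactions)
            if s >= minsup_ratio - _EPS:
                rule.support = s
                out.append(rule)
    return out


# ---------------------------------------------------------------------
# Closedness
# ---------------------------------------------------------------------

def _unification_signature(rule: Rule):
    u = rule.unification
    if u is None:
        return None
    mps = rule.metapaths
    return (mps[u.i], u.position_i, mps[u.j], u.position_j)


def _is_strict_subpattern(a: Rule, b: Rule) -> bool:
    if not (a.items <= b.items):
        return False
    sig_a = _unification_signature(a)
    sig_b = _unification_signature(b)
    if sig_a is not None and sig_a != sig_b:
        return False
    return a.items < b.items or (sig_a is None and sig_b is not None)


def closed_only(rules: Sequence[Rule]) -> List[Rule]:
    """Keep only closed patterns: drop a rule when a strict super-pattern in
    the set has the same support (within 1e-12)."""
    kept: List[Rule] = []
    for a in rules:
        dominated = any(
            _is_strict_subpattern(a, b)
            and abs(a.support - b.support) <= _EPS
            for b in rules
        )
        if not dominated:
            kept.append(a)
    return kept


# ---------------------------------------------------------------------
# Confidence
# ---------------------------------------------------------------------

def rule_confidence(rule: Rule, D: Sequence[Transaction],
                    N: Sequence[Transaction]) -> float:
    """Imbalance-corrected precision of the rule against the positive (D)
    and neutral (N) sets: |C_r(D)| / (|C_r(D)| + (|D|/|N|)·|C_r(N)|), all
    quantities being sums of instance weights."""
    cov_d = sum(t.weight for t in D if matches(rule, t.index))
    cov_n = sum(t.weight for t in N if matches(rule, t.index))
    if cov_d + cov_n <= 0:
        raise ValueError("rule covers no instance; confidence undefined")
    size_d = sum(t.weight for t in D)
    size_n = sum(t.weight for t in N)
    return cov_d / (cov_d + (size_d / size_n) * cov_n)
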
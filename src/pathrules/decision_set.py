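"""Decision-set training: greedy weighted set cover over mined rules and
class-probability estimation.

A candidate rule set R gets the weight

    w(R) = alpha * (1 - |C_R(D)|/|D|) + (1 - alpha) * |C_R(N)|/|N|

(all quantities weighted sums of instances; C_R is the union of per-rule
coverages), so low weight means high positive and low negative coverage.
Greedy selection repeatedly adds the rule of minimum marginal weight
w(R + r) - w(R) and stops when no rule still decreases w.  Each selected
rule then carries the imbalance-corrected precision

    p(l_D | r) = |C_r(D)| / (|C_r(D)| + (|D|/|N|) * |C_r(N)|)

used as its positive class probability; pairs matching no rule get a
default probability estimated the same way from the uncovered remainder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .paths import GenePairPathIndex, Metapath, MetapathStep
from .rules import Rule, Transaction, UnificationConstraint, matches

__all__ = [
    "set_weight",
    "marginal_weight",
    "greedy_select",
    "rule_probability",
    "default_negative_probability",
    "DecisionSetModel",
    "train_decision_set",
]


def _coverage_masks(rules: Sequence[Rule], D: Sequence[Transaction],
                    N: Sequence[Transaction]
                    ) -> Tuple[np.ndarray, np.ndarray]:
    cov_d = np.zeros((len(rules), len(D)), dtype=bool)
    cov_n = np.zeros((len(rules), len(N)), dtype=bool)
    for ri, r in enumerate(rules):
        for ti, t in enumerate(D):
            cov_d[ri, ti] = matches(r, t.index)
        for ti, t in enumerate(N):
            cov_n[ri, ti] = matches(r, t.index)
    return cov_d, cov_n


def set_weight(R: Sequence[Rule], D: Sequence[Transaction],
               N: Sequence[Transaction], alpha: float = 0.5) -> float:
    """Weight of a candidate rule set (lower is better)."""
    if not D or not N:
        raise ValueError("both D and N must be non-empty")
    w_d = np.array([t.weight for t in D])
    w_n = np.array([t.weight for t in N])
    cov_d = np.zeros(len(D), dtype=bool)
    cov_n = np.zeros(len(N), dtype=bool)
    for r in set(R):
        for ti, t in enumerate(D):
            if not cov_d[ti]:
                cov_d[ti] = matches(r, t.index)
        for ti, t in enumerate(N):
            if not cov_n[ti]:
                cov_n[ti] = matches(r, t.index)
    return float(
        alpha * (1.0 - w_d[cov_d].sum() / w_d.sum())
        + (1.0 - alpha) * (w_n[cov_n].sum() / w_n.sum())
    )


def marginal_weight(r: Rule, R: Sequence[Rule], D: Sequence[Transaction],
                    N: Sequence[Transaction], alpha: float = 0.5) -> float:
    """w(R + r) - w(R); zero when r adds no new coverage."""
    return set_weight(list(R) + [r], D, N, alpha) - set_weight(R, D, N, alpha)


def rule_probability(r: Rule, D: Sequence[Transaction],
                     N: Sequence[Transaction]) -> float:
    """Imbalance-corrected precision used as p(l_D | r)."""
    from .rules import rule_confidence

    return rule_confidence(r, D, N)


def default_negative_probability(R: Sequence[Rule], D: Sequence[Transaction],
                                 N: Sequence[Transaction]) -> float:
    """Probability for pairs matching no rule, from uncovered instances."""
    unc_d = sum(t.weight for t in D
                if not any(matches(r, t.index) for r in R))
    unc_n = sum(t.weight for t in N
                if not any(matches(r, t.index) for r in R))
    if unc_d + unc_n <= 0:
        return 0.0
    size_d = sum(t.weight for t in D)
    size_n = sum(t.weight for t in N)
    return unc_d / (unc_d + (size_d / size_n) * unc_n)


def greedy_select(rules: Sequence[Rule], D: Sequence[Transaction],
                  N: Sequence[Transaction], alpha: float = 0.5) -> List[Rule]:
    """Greedy weighted set cover.

    Ties on marginal weight break towards the rule of higher class
    probability, then lexicographic rule serialization, so the trace is
    deterministic.
    """
    if not rules:
        raise ValueError("no candidate rules")
    cov_d, cov_n = _coverage_masks(rules, D, N)
    w_d = np.array([t.weight for t in D])
    w_n = np.array([t.weight for t in N])
    sum_d, sum_n = w_d.sum(), w_n.sum()

    probs = np.empty(len(rules))
    for ri in range(len(rules)):
        cd = w_d[cov_d[ri]].sum()
        cn = w_n[cov_n[ri]].sum()
        probs[ri] = cd / (cd + (sum_d / sum_n) * cn) if cd + cn > 0 else 0.0

    selected: List[int] = []
    covered_d = np.zeros(len(D), dtype=bool)
    covered_n = np.zeros(len(N), dtype=bool)
    remaining = set(range(len(rules)))
    while remaining:
        best_ri = None
        best_key = None
        for ri in remaining:
            new_d = w_d[cov_d[ri] & ~covered_d].sum()
            new_n = w_n[cov_n[ri] & ~covered_n].sum()
            marginal = -alpha * new_d / sum_d + (1 - alpha) * new_n / sum_n
            key = (marginal, -probs[ri], rules[ri].sort_key())
            if best_key is None or key < best_key:
                best_key = key
                best_ri = ri
        assert best_ri is not None
        if best_key[0] >= 0.0:
            break
        selected.append(best_ri)
        covered_d |= cov_d[best_ri]
        covered_n |= cov_n[best_ri]
        remaining.discard(best_ri)
    return [rules[ri] for ri in selected]


# ---------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------

@dataclass
class DecisionSetModel:
    """Unordered rule collection with per-rule probabilities: the trained
    classifier.  Prediction takes the highest-probability matching rule, or
    the default negative probability when nothing matches."""

    rules: List[Rule]
    alpha: float
    default_negative: float
    metadata: Dict[str, object] = field(default_factory=dict)

    def predict(self, index: GenePairPathIndex
                ) -> Tuple[float, List[Rule]]:
        matched = [r for r in self.rules if matches(r, index)]
        matched.sort(key=lambda r: (-r.probability, r.sort_key()))
        if not matched:
            return self.default_negative, []
        return matched[0].probability, matched

    # -- serialization ------------------------------------------------
    def to_dict(self) -> Dict:
        return {
            "alpha": self.alpha,
            "default_negative": self.default_negative,
            "metadata": self.metadata,
            "rules": [_rule_to_dict(r) for r in self.rules],
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "DecisionSetModel":
        return cls(
            rules=[_rule_from_dict(rd) for rd in d["rules"]],
            alpha=d["alpha"],
            default_negative=d["default_negative"],
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "DecisionSetModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _rule_to_dict(r: Rule) -> Dict:
    d: Dict = {
        "text": r.to_text(),
        "conditions": [
            {"steps": [[s.metaedge, s.forward] for s in mp.steps],
             "theta": theta}
            for mp, theta in r.conditions
        ],
        "support": r.support,
        "confidence": r.confidence,
        "probability": r.probability,
    }
    if r.unification is not None:
        u = r.unification
        d["unification"] = {"i": u.i, "position_i": u.position_i,
                            "j": u.j, "position_j": u.position_j,
                            "node_type": u.node_type}
    return d


def _rule_from_dict(d: Dict) -> Rule:
    conds = tuple(
        (Metapath(tuple(MetapathStep(m, f) for m, f in c["steps"])),
         float(c["theta"]))
        for c in d["conditions"]
    )
    u = None
    if "unification" in d:
        ud = d["unification"]
        u = UnificationConstraint(ud["i"], ud["position_i"], ud["j"],
                                  ud["position_j"], ud["node_type"])
    rule = Rule(conds, u)
    rule.support = d.get("support", float("nan"))
    rule.confidence = d.get("confidence", float("nan"))
    rule.probability = d.get("probability", float("nan"))
    return rule


def train_decision_set(rules: Sequence[Rule], D: Sequence[Transaction],
                       N: Sequence[Transaction], alpha: float = 0.5,
                       metadata: Optional[Dict] = None) -> DecisionSetModel:
    """Select rules by greedy set cover and calibrate probabilities."""
    selected = greedy_select(rules, D, N, alpha)
    for r in selected:
        r.probability = rule_probability(r, D, N)
    return DecisionSetModel(
        rules=selected,
        alpha=alpha,
        default_negative=default_negative_probability(selected, D, N),
        metadata=metadata or {},
    )
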
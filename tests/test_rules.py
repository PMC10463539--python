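"""Rule mining: matching semantics, weighted Apriori vs brute force,
unification, closedness, confidence."""

from itertools import combinations

import numpy as np
import pytest

from pathrules.rules import (Rule, Transaction, UnificationConstraint,
                             apriori_mine, closed_only,
                             extend_with_unifications, matches,
                             rule_confidence, rule_from_itemset,
                             weighted_support)
from pathrules.simulate import metapath

from conftest import MP_GaBPaG, MP_GaBPaGpG, MP_GaMFaG, MP_GpG, \
    make_index, make_transactions


def brute_force_itemsets(transactions, minsup, max_len):
    """Independent oracle: enumerate every subset of the item universe."""
    universe = sorted({mp for t in transactions for mp in t.items},
                      key=lambda m: m.sort_key())
    total = sum(t.weight for t in transactions)
    out = {}
    for k in range(1, max_len + 1):
        for combo in combinations(universe, k):
            s = sum(t.weight for t in transactions
                    if set(combo) <= t.items) / total
            if s >= minsup - 1e-12:
                out[frozenset(combo)] = s
    return out


class TestMatching:
    def test_threshold_gates_matching(self):
        index = make_index(("a", "b"), {MP_GpG: [(0.9, ("a", "b"))]})
        rule_lo = rule_from_itemset([MP_GpG], thetas=[0.5])
        rule_hi = rule_from_itemset([MP_GpG], thetas=[0.95])
        assert matches(rule_lo, index)
        assert not matches(rule_hi, index)

    def test_unification_requires_shared_node(self):
        uni = UnificationConstraint(0, 1, 1, 1, "BiologicalProcess")
        rule = rule_from_itemset([MP_GaBPaG, MP_GaBPaGpG], unification=uni)
        disjoint = make_index(("a", "b"), {
            MP_GaBPaG: [(0.9, ("a", "bp1", "b"))],
            MP_GaBPaGpG: [(0.9, ("a", "bp2", "x", "b"))],
        })
        shared = make_index(("a", "b"), {
            MP_GaBPaG: [(0.9, ("a", "bp1", "b"))],
            MP_GaBPaGpG: [(0.9, ("a", "bp2", "x", "b")),
                          (0.8, ("a", "bp1", "y", "b"))],
        })
        assert not matches(rule, disjoint)
        assert matches(rule, shared)

    def test_all_conditions_required(self):
        rule = rule_from_itemset([MP_GpG, MP_GaBPaG])
        index = make_index(("a", "b"), {MP_GpG: [(0.9, ("a", "b"))]})
        assert not matches(rule, index)


class TestAprioriMine:
    def unit_transactions(self):
        m1, m2 = MP_GpG, MP_GaBPaG
        return make_transactions([
            (1.0, {m1: [(1.0, ("a", "b"))]}),
            (1.0, {m1: [(1.0, ("a", "b"))]}),
            (1.0, {m1: [(1.0, ("a", "b"))],
                   m2: [(1.0, ("a", "bp0", "b"))]}),
            (1.0, {m2: [(1.0, ("a", "bp0", "b"))]}),
        ])

    def test_hand_worked_supports(self):
        got = dict(apriori_mine(self.unit_transactions(), 0.5, 3))
        assert got == {
            frozenset([MP_GpG]): pytest.approx(0.75),
            frozenset([MP_GaBPaG]): pytest.approx(0.5),
        }

    def test_tiny_minsup_returns_full_powerset(self):
        got = dict(apriori_mine(self.unit_transactions(), 1e-9, 3))
        assert set(got) == {
            frozenset([MP_GpG]), frozenset([MP_GaBPaG]),
            frozenset([MP_GpG, MP_GaBPaG]),
        }
        assert got[frozenset([MP_GpG, MP_GaBPaG])] == pytest.approx(0.25)

    def test_weighted_supports_against_oracle(self):
        txns = self.unit_transactions()
        weighted = [Transaction(t.pair_id, w, t.items, t.index)
                    for t, w in zip(txns, (1.0, 1.0, 0.2, 0.2))]
        got = dict(apriori_mine(weighted, 0.05, 3))
        expected = brute_force_itemsets(weighted, 0.05, 3)
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-12)

    def test_support_is_antimonotone(self):
        got = dict(apriori_mine(self.unit_transactions(), 1e-9, 3))
        for items, sup in got.items():
            for sub in combinations(items, len(items) - 1):
                if sub:
                    assert got[frozenset(sub)] >= sup - 1e-12

    def test_empty_transactions_raise(self):
        with pytest.raises(ValueError):
            apriori_mine([], 0.2, 3)


class TestUnificationMining:
    def planted_transactions(self):
        shared = {
            MP_GaBPaG: [(0.9, ("a", "bpS", "b"))],
            MP_GaBPaGpG: [(0.9, ("a", "bpS", "x", "b"))],
        }
        disjoint = {
            MP_GaBPaG: [(0.9, ("a", "bp1", "b"))],
            MP_GaBPaGpG: [(0.9, ("a", "bp2", "x", "b"))],
        }
        return make_transactions(
            [(1.0, shared), (1.0, shared), (1.0, shared), (1.0, disjoint)])

    def test_planted_unification_found_with_support(self):
        txns = self.planted_transactions()
        itemsets = apriori_mine(txns, 0.5, 3)
        unified = extend_with_unifications(itemsets, txns, 0.5)
        assert len(unified) == 1
        rule = unified[0]
        assert rule.unification.node_type == "BiologicalProcess"
        assert rule.support == pytest.approx(0.75)
        # brute-force check of the support via the matcher
        assert weighted_support(rule, txns) == pytest.approx(0.75)

    def test_no_shared_nodes_no_unified_rules(self):
        txns = make_transactions([
            (1.0, {MP_GaBPaG: [(0.9, ("a", "bp1", "b"))],
                   MP_GaBPaGpG: [(0.9, ("a", "bp2", "x", "b"))]}),
        ] * 3)
        itemsets = apriori_mine(txns, 0.5, 3)
        assert extend_with_unifications(itemsets, txns, 0.5) == []

    def test_endpoint_genes_are_not_candidates(self):
        # gene-type positions exist only at intermediates; a pair of
        # length-1 metapaths offers no candidate at all
        itemsets = [(frozenset([MP_GpG, metapath([("GsG", True)])]), 1.0)]
        txns = make_transactions([
            (1.0, {MP_GpG: [(0.9, ("a", "b"))],
                   metapath([("GsG", True)]): [(0.9, ("a", "b"))]}),
        ])
        assert extend_with_unifications(itemsets, txns, 0.1) == []


class TestClosedOnly:
    def rule(self, items, support, uni=None):
        r = rule_from_itemset(items, unification=uni)
        r.support = support
        return r

    def test_subset_with_equal_support_dropped(self):
        r1 = self.rule([MP_GpG], 0.75)
        r2 = self.rule([MP_GpG, MP_GaBPaG], 0.75)
        assert closed_only([r1, r2]) == [r2]

    def test_subset_with_larger_support_kept(self):
        r1 = self.rule([MP_GpG], 0.75)
        r2 = self.rule([MP_GpG, MP_GaBPaG], 0.5)
        assert closed_only([r1, r2]) == [r1, r2]

    def test_randomized_against_brute_force(self):
        rng = np.random.default_rng(3)
        universe = [MP_GpG, MP_GaBPaG, MP_GaMFaG, MP_GaBPaGpG]
        for _ in range(25):
            rules = []
            seen = set()
            for _ in range(rng.integers(2, 10)):
                k = int(rng.integers(1, len(universe) + 1))
                items = frozenset(
                    rng.choice(len(universe), size=k, replace=False))
                if items in seen:
                    continue
                seen.add(items)
                rules.append(self.rule([universe[i] for i in items],
                                       float(rng.choice([0.25, 0.5, 0.75]))))
            got = closed_only(rules)
            expected = [
                a for a in rules
                if not any(a.items < b.items and a.support == b.support
                           for b in rules)
            ]
            assert got == expected


class TestRuleConfidence:
    def txn(self, weight, has_item):
        paths = {MP_GpG: [(1.0, ("a", "b"))]} if has_item else {}
        return make_transactions([(weight, paths)])[0]

    def test_positive_only_coverage_is_one(self):
        rule = rule_from_itemset([MP_GpG])
        D = [self.txn(1.0, True)] * 3
        N = [self.txn(1.0, False)] * 3
        assert rule_confidence(rule, D, N) == pytest.approx(1.0)

    def test_negative_only_coverage_is_zero(self):
        rule = rule_from_itemset([MP_GpG])
        D = [self.txn(1.0, False)] * 3
        N = [self.txn(1.0, True)] * 3
        assert rule_confidence(rule, D, N) == pytest.approx(0.0)

    def test_imbalance_corrected_arithmetic(self):
        rule = rule_from_itemset([MP_GpG])
        D = [self.txn(1.0, i < 20) for i in range(100)]
        N = [self.txn(1.0, i < 200) for i in range(10_000)]
        # 20 / (20 + (100/10000) * 200) = 0.909090...
        assert rule_confidence(rule, D, N) == pytest.approx(20 / 22)

    def test_zero_coverage_raises(self):
        rule = rule_from_itemset([MP_GpG])
        with pytest.raises(ValueError):
            rule_confidence(rule, [self.txn(1.0, False)],
                            [self.txn(1.0, False)])


def test_rule_text_rendering():
    uni = UnificationConstraint(0, 1, 1, 1, "BiologicalProcess")
    rule = rule_from_itemset([MP_GaBPaG, MP_GaBPaGpG], unification=uni,
                             thetas=[0.21, 0.5])
    assert rule.to_text() == "GaBPaG >= 0.21 & GaBPaGpG >= 0.50 | BP1=BP2"
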
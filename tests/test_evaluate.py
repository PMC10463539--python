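"""Evaluation utilities: threshold selection, curve averaging, RWR
baseline, metapath influence, connectivity ratios, stratified CV."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from pathrules.evaluate import (FoldResult, average_curves,
                                connectivity_ratio, metapath_influence,
                                optimal_threshold, rwr_baseline,
                                stratified_cv)
from pathrules.graph import Edge, KnowledgeGraph, Node
from pathrules.rules import rule_from_itemset

from conftest import MP_GaBPaG, MP_GaMFaG, MP_GpG


class TestOptimalThreshold:
    def test_perfect_point_selected(self):
        fpr = np.array([0.0, 0.0, 1.0])
        tpr = np.array([0.0, 1.0, 1.0])
        thr = np.array([np.inf, 0.5, 0.0])
        t, g = optimal_threshold(fpr, tpr, thr)
        assert t == 0.5 and g == pytest.approx(1.0)

    def test_zero_sensitivity_gives_zero_gmean(self):
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 0.0])
        _, g = optimal_threshold(fpr, tpr, np.array([1.0, 0.0]))
        assert g == 0.0

    def test_hand_value_and_scan_oracle(self):
        fpr = np.array([0.0, 0.066, 0.3, 1.0])
        tpr = np.array([0.4, 0.818, 0.9, 1.0])
        thr = np.array([0.9, 0.62, 0.3, 0.0])
        t, g = optimal_threshold(fpr, tpr, thr)
        assert g == pytest.approx(np.sqrt(0.818 * 0.934), abs=1e-3)
        assert t == 0.62
        # exhaustive scan oracle
        best = max(np.sqrt(tp * (1 - fp)) for tp, fp in zip(tpr, fpr))
        assert g == pytest.approx(best)


class TestAverageCurves:
    def fold(self, y, s):
        return FoldResult(0, np.asarray(y), np.asarray(s), np.ones(len(y)))

    def test_identical_folds_have_zero_spread(self):
        f = self.fold([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        curves = average_curves([f, f, f])
        assert np.allclose(curves["std_tpr"], 0.0)
        assert curves["auroc_std"] == 0.0
        assert curves["auroc_mean"] == pytest.approx(f.auroc)

    def test_perfect_classifier_auroc_one(self):
        f = self.fold([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        curves = average_curves([f, f])
        assert curves["auroc_mean"] == pytest.approx(1.0)
        assert curves["auroc_mean_curve"] == pytest.approx(1.0, abs=0.02)

    def test_two_hand_built_folds_average(self):
        f1 = self.fold([0, 1], [0.2, 0.8])  # perfect: tpr 1 everywhere
        f2 = self.fold([1, 0], [0.2, 0.8])  # inverted: tpr 0 until fpr 1
        curves = average_curves([f1, f2])
        # mean tpr at interior fpr grid points is (1 + 0)/2
        interior = curves["mean_tpr"][1:-1]
        assert np.allclose(interior, 0.5)


class TestRWR:
    def two_node_kg(self):
        kg = KnowledgeGraph()
        kg.add_node(Node("g1", "Gene"))
        kg.add_node(Node("g2", "Gene"))
        kg.add_edge(Edge("g1", "g2", "GpG", score=0.9))
        return kg

    def test_two_node_closed_form(self):
        # p = r e + (1-r) W p with W swapping the two states:
        # p_tgt = (1-r) r / (1 - (1-r)^2)
        kg = self.two_node_kg()
        r = 0.7
        expected = (1 - r) * r / (1 - (1 - r) ** 2)
        assert rwr_baseline(kg, ("g1", "g2"), restart=r) == pytest.approx(
            expected, abs=1e-9)

    def test_restart_one_scores_zero(self):
        kg = self.two_node_kg()
        assert rwr_baseline(kg, ("g1", "g2"), restart=1.0) == 0.0

    def test_disconnected_pair_scores_zero(self):
        kg = self.two_node_kg()
        kg.add_node(Node("g3", "Gene"))
        assert rwr_baseline(kg, ("g1", "g3")) == 0.0

    def test_symmetric_in_pair_order(self):
        kg = self.two_node_kg()
        kg.add_node(Node("g3", "Gene"))
        kg.add_edge(Edge("g2", "g3", "GpG"))
        a = rwr_baseline(kg, ("g1", "g3"))
        b = rwr_baseline(kg, ("g3", "g1"))
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 < a < 1.0


class TestMetapathInfluence:
    def rule(self, items, confidence):
        r = rule_from_itemset(items)
        r.confidence = confidence
        return r

    def test_identical_distributions_not_reported(self):
        rules = [self.rule([MP_GpG], 0.5), self.rule([MP_GaBPaG], 0.5),
                 self.rule([MP_GpG, MP_GaBPaG], 0.5),
                 self.rule([MP_GaMFaG], 0.5)]
        assert metapath_influence(rules).empty

    def test_complete_separation_gives_rank_biserial_one(self):
        rules = (
            [self.rule([MP_GpG], 0.9)] * 8 + [self.rule([MP_GaBPaG], 0.1)] * 8
        )
        df = metapath_influence(rules, max_adj_p=0.05)
        row = df.set_index("metapath").loc["GpG"]
        assert row["rank_biserial"] == pytest.approx(1.0)

    def test_statistics_match_brute_force_u(self):
        rng = np.random.default_rng(9)
        rules = []
        for i in range(10):
            items = [MP_GpG] if i < 5 else [MP_GaBPaG]
            if rng.random() < 0.5:
                items.append(MP_GaMFaG)
            rules.append(self.rule(items, float(rng.uniform(0, 1))))
        df = metapath_influence(rules, max_adj_p=1.0)
        confid = np.array([r.confidence for r in rules])
        candidates = [mp for mp in (MP_GpG, MP_GaBPaG, MP_GaMFaG)
                      if 0 < sum(mp in r.items for r in rules) < len(rules)]
        tested = len(candidates)
        for mp in candidates:
            has = np.array([mp in r.items for r in rules])
            x, y = confid[has], confid[~has]
            # brute-force U statistic: count pairwise wins
            u = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
            rb = 2 * u / (len(x) * len(y)) - 1
            row = df.set_index("metapath").loc[mp.abbreviation]
            assert row["rank_biserial"] == pytest.approx(rb)
            _, p = mannwhitneyu(x, y, alternative="greater")
            assert row["adj_p"] == pytest.approx(min(p * tested, 1.0))

    def test_too_few_rules_raise(self):
        with pytest.raises(ValueError):
            metapath_influence([self.rule([MP_GpG], 0.5)])


class TestConnectivityRatio:
    def chain_kg(self):
        kg = KnowledgeGraph()
        for i in range(5):
            kg.add_node(Node(f"g{i}", "Gene"))
        for i in range(4):
            kg.add_edge(Edge(f"g{i}", f"g{i+1}", "GpG"))
        return kg

    def test_direct_pairs_at_cutoff_one(self):
        kg = self.chain_kg()
        df = connectivity_ratio(kg, [("g0", "g1"), ("g1", "g2")],
                                cutoffs=[1])
        assert df["ratio"].tolist() == [1.0]

    def test_empty_metaedge_subset_zero(self):
        kg = self.chain_kg()
        df = connectivity_ratio(kg, [("g0", "g1")], metaedge_subset=[],
                                cutoffs=[1, 2])
        assert df["ratio"].tolist() == [0.0, 0.0]

    def test_monotone_in_cutoff_and_matches_bfs(self):
        kg = self.chain_kg()
        pairs = [("g0", "g1"), ("g0", "g2"), ("g0", "g4"), ("g1", "g3")]
        df = connectivity_ratio(kg, pairs, cutoffs=[1, 2, 3, 4])
        ratios = df["ratio"].tolist()
        assert ratios == sorted(ratios)
        # chain distances: 1, 2, 4, 2 -> ratios 0.25, 0.75, 0.75, 1.0
        assert ratios == pytest.approx([0.25, 0.75, 0.75, 1.0])


class TestStratifiedCV:
    def test_fold_class_ratio_and_determinism(self):
        from conftest import make_index

        rng = np.random.default_rng(1)
        # 10 positives carrying the signal metapath, 100 negatives without
        X = []
        y = []
        for i in range(10):
            X.append(make_index((f"p{i}", f"q{i}"),
                                {MP_GpG: [(0.9, (f"p{i}", f"q{i}"))]}))
            y.append(1)
        for i in range(100):
            X.append(make_index((f"n{i}", f"m{i}"), {}))
            y.append(0)
        folds = stratified_cv(X, y, k=10, seed=0, optimize=False,
                              unification=False)
        assert len(folds) == 10
        for f in folds:
            assert f.y_true.sum() == 1 and len(f.y_true) == 11
            assert f.auroc == pytest.approx(1.0)
        folds2 = stratified_cv(X, y, k=10, seed=0, optimize=False,
                               unification=False)
        assert all(np.array_equal(a.y_score, b.y_score)
                   for a, b in zip(folds, folds2))
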
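"""Edge-scoring formulas: functional information, SimGIC, BSR,
co-expression filtering, protein-to-gene collapsing."""

import math

import numpy as np
import pytest

from pathrules.scoring import (CoexpressionRecord, OntologyHierarchy,
                               blast_score_ratio, collapse_to_genes,
                               filter_coexpression, functional_information,
                               phenotype_frequency_score, simgic)


@pytest.fixture
def small_ontology():
    # root <- a <- c ; root <- b
    return OntologyHierarchy(
        terms={"root", "a", "b", "c"},
        is_a={"a": {"root"}, "b": {"root"}, "c": {"a"}},
        annotations={
            "root": {f"g{i}" for i in range(100)},
            "a": {f"g{i}" for i in range(10)},
            "b": {"g0"},
            "c": {"g1"},
        },
    )


class TestFunctionalInformation:
    def test_term_covering_all_genes_scores_zero(self, small_ontology):
        assert functional_information("root", small_ontology) == pytest.approx(0.0)

    def test_single_gene_term_scores_one(self, small_ontology):
        assert functional_information("b", small_ontology) == pytest.approx(1.0)

    def test_ten_of_hundred_scores_half(self, small_ontology):
        # -log(10/100)/log(100) = 1/2, in any log base
        assert functional_information("a", small_ontology) == pytest.approx(0.5)

    def test_subterm_genes_are_included(self):
        h = OntologyHierarchy(
            terms={"t", "s"}, is_a={"s": {"t"}},
            annotations={"t": {"g1"}, "s": {"g2", "g3"},
                         },
        )
        # t's gene set includes its subterm s: 3 genes of 3 -> FI 0
        assert functional_information("t", h) == pytest.approx(0.0)

    def test_unannotated_term_raises(self):
        h = OntologyHierarchy(terms={"t", "u"}, is_a={},
                              annotations={"t": {"g1", "g2"}})
        with pytest.raises(ValueError, match="annotates no genes"):
            functional_information("u", h)

    def test_monotone_in_annotation_set_size(self, small_ontology):
        fis = [functional_information(t, small_ontology)
               for t in ("root", "a", "b")]  # 100, 10, 1 genes
        assert fis == sorted(fis)


class TestSimgic:
    def test_identical_terms(self, small_ontology):
        ic = {"root": 0.0, "a": 1.0, "b": 2.0, "c": 3.0}
        assert simgic("c", "c", small_ontology, ic) == pytest.approx(1.0)

    def test_only_zero_ic_root_shared(self, small_ontology):
        ic = {"root": 0.0, "a": 1.0, "b": 2.0, "c": 3.0}
        assert simgic("a", "b", small_ontology, ic) == pytest.approx(0.0)

    def test_hand_computed_ratio(self, small_ontology):
        ic = {"root": 0.5, "a": 1.0, "b": 2.0, "c": 3.0}
        # ancestors(c)={c,a,root}, ancestors(a)={a,root}
        # shared {a,root}=1.5 ; union {c,a,root}=4.5
        assert simgic("c", "a", small_ontology, ic) == pytest.approx(1.5 / 4.5)

    def test_symmetry(self, small_ontology):
        ic = {"root": 0.5, "a": 1.0, "b": 2.0, "c": 3.0}
        assert simgic("c", "b", small_ontology, ic) == \
            simgic("b", "c", small_ontology, ic)

    def test_zero_union_raises(self):
        h = OntologyHierarchy(terms={"x", "y"}, is_a={}, annotations={})
        with pytest.raises(ValueError):
            simgic("x", "y", h, {})

    def test_cyclic_hierarchy_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            OntologyHierarchy(terms={"a", "b"},
                              is_a={"a": {"b"}, "b": {"a"}}, annotations={})


class TestBlastScoreRatio:
    def test_self_alignment_is_one(self):
        assert blast_score_ratio(400, 400, 400, 1.0) == pytest.approx(1.0)

    def test_low_coverage_gated(self):
        assert blast_score_ratio(120, 400, 300, 0.3) is None

    def test_hand_value(self):
        assert blast_score_ratio(120, 400, 300, 0.8) == pytest.approx(0.4)

    def test_clamped_at_one(self):
        assert blast_score_ratio(500, 400, 450, 0.9) == pytest.approx(1.0)

    def test_nonpositive_self_score_raises(self):
        with pytest.raises(ValueError):
            blast_score_ratio(10, 0.0, 5.0, 0.9)


class TestCoexpressionFilter:
    def rec(self, **kw):
        base = dict(gene_a="g1", gene_b="g2", tissue="liver", rho=0.9,
                    adj_p=0.001, n_samples=100, z_a=0.0, z_b=0.0)
        base.update(kw)
        return CoexpressionRecord(**base)

    def test_single_passing_record(self):
        edges = filter_coexpression([self.rec()])
        assert len(edges) == 1
        e = edges[0]
        assert e.metaedge == "GeG"
        assert e.score == pytest.approx(0.9)
        assert e.tissues == frozenset({"liver"})

    @pytest.mark.parametrize("kw", [
        dict(z_a=-4.0),                 # expression-outlier gate
        dict(n_samples=50),             # sample-size gate
        dict(adj_p=0.05),               # significance gate
        dict(rho=0.5),                  # correlation gate
    ])
    def test_gates_drop_records(self, kw):
        assert filter_coexpression([self.rec(**kw)]) == []

    def test_max_correlation_and_tissue_union(self):
        edges = filter_coexpression([
            self.rec(tissue="liver", rho=0.82),
            self.rec(tissue="heart", rho=0.91),
        ])
        assert len(edges) == 1
        assert edges[0].score == pytest.approx(0.91)
        assert edges[0].tissues == frozenset({"liver", "heart"})

    def test_fisher_adjustment_relaxes_with_small_n(self):
        # rho slightly below 0.80 passes at the minimum sample size but
        # not at a very large one
        r_small = self.rec(rho=0.78, n_samples=70)
        r_large = self.rec(rho=0.78, n_samples=100_000)
        assert len(filter_coexpression([r_small])) == 1
        assert filter_coexpression([r_large]) == []

    def test_brute_force_refilter_oracle(self):
        rng = np.random.default_rng(7)
        records = [
            self.rec(
                gene_a=f"g{rng.integers(4)}", gene_b=f"h{rng.integers(4)}",
                tissue=["liver", "heart", "brain"][rng.integers(3)],
                rho=float(rng.uniform(0.5, 1.0)),
                adj_p=float(rng.uniform(0, 0.05)),
                n_samples=int(rng.integers(40, 200)),
                z_a=float(rng.normal()), z_b=float(rng.normal()),
            )
            for _ in range(200)
        ]
        edges = filter_coexpression(records)
        # every output edge is reproduced by independently re-filtering
        surviving = {}
        from math import atanh, sqrt
        from scipy.stats import norm
        zc = norm.ppf(0.99)
        for r in records:
            if r.n_samples < 70 or r.z_a < -3 or r.z_b < -3:
                continue
            if not r.adj_p < 0.01:
                continue
            if atanh(r.rho) < atanh(0.80) - zc / sqrt(r.n_samples - 3):
                continue
            key = tuple(sorted((r.gene_a, r.gene_b)))
            surviving.setdefault(key, []).append(r)
        assert len(edges) == len(surviving)
        for e in edges:
            recs = surviving[(e.source, e.target)]
            assert e.score == pytest.approx(max(r.rho for r in recs))
            assert e.tissues == {r.tissue for r in recs}


class TestCollapseToGenes:
    MAP = {"p1": "gA", "p2": "gA", "p3": "gB", "p4": "gC"}

    def test_max_score_collapse(self):
        edges, _ = collapse_to_genes(
            [("p1", "p3", "GpG", 0.3), ("p2", "p3", "GpG", 0.7)], self.MAP)
        assert len(edges) == 1
        assert edges[0].score == pytest.approx(0.7)

    def test_self_edge_dropped(self):
        edges, report = collapse_to_genes([("p1", "p2", "GpG", 0.9)], self.MAP)
        assert edges == []
        assert report["self_edges_dropped"] == 1

    def test_unmapped_counted(self):
        edges, report = collapse_to_genes([("p1", "px", "GpG", 0.9)], self.MAP)
        assert edges == []
        assert report["unmapped_skipped"] == 1

    def test_hand_collapsed_table(self):
        table = [("p1", "p3", "GpG", 0.2), ("p2", "p3", "GpG", 0.5),
                 ("p3", "p4", "GpG", 0.9), ("p1", "p4", "GsG", 0.4)]
        edges, _ = collapse_to_genes(table, self.MAP)
        got = {(e.source, e.target, e.metaedge): e.score for e in edges}
        assert got == {("gA", "gB", "GpG"): 0.5, ("gB", "gC", "GpG"): 0.9,
                       ("gA", "gC", "GsG"): 0.4}


def test_phenotype_frequency_midpoints():
    assert phenotype_frequency_score("Obligate") == 1.0
    assert phenotype_frequency_score("Very frequent") == pytest.approx(0.895)
    assert phenotype_frequency_score(None) is None
    assert phenotype_frequency_score("no idea") is None
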
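"""Scikit-learn style estimators wrapping the full training workflow.

``PathFeaturizer`` is a stateless transformer turning gene pairs into
per-pair path indexes over a knowledge graph; ``DecisionSetClassifier``
fits the associative classifier (Apriori mining of metapath itemsets with
weighted support, optional unification extension, closed-pattern
reduction, per-rule reliability-threshold optimization by differential
evolution, and greedy weighted set cover) and predicts pathogenicity
probabilities.  The two compose in a standard sklearn Pipeline.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .decision_set import DecisionSetModel, train_decision_set
from .graph import KnowledgeGraph
from .paths import (DEFAULT_EXCLUDED_NODE_TYPES, GenePairPathIndex,
                    enumerate_paths, order_pair)
from .rules import (Rule, Transaction, apriori_mine, closed_only,
                    extend_with_unifications, rule_confidence,
                    rule_from_itemset)
from .thresholds import FitnessContext, optimize_thresholds

__all__ = ["PathFeaturizer", "DecisionSetClassifier", "featurize_pairs"]


def featurize_pairs(
    kg: KnowledgeGraph,
    pairs: Iterable[Tuple[str, str]],
    path_cutoff: int = 3,
    excluded_node_types: Iterable[str] = DEFAULT_EXCLUDED_NODE_TYPES,
) -> List[GenePairPathIndex]:
    """Order each gene pair by RVIS and enumerate its admissible paths."""
    out = []
    excluded = tuple(excluded_node_types)
    for a, b in pairs:
        src, tgt = order_pair(kg.nodes[a], kg.nodes[b])
        out.append(enumerate_paths(kg, (src.uri, tgt.uri),
                                   path_cutoff=path_cutoff,
                                   excluded_node_types=excluded))
    return out


class PathFeaturizer(TransformerMixin, BaseEstimator):
    """Transform (gene_a, gene_b) pairs into path indexes on a fixed graph.

    Parameters
    ----------
    kg:
        the knowledge graph to traverse.
    path_cutoff:
        maximum path length in edges (default 3).
    exclude_phenotype:
        additionally skip Phenotype intermediates (the phenotype-exclusive
        setting that avoids annotation-coverage bias).
    """

    def __init__(self, kg: Optional[KnowledgeGraph] = None,
                 path_cutoff: int = 3, exclude_phenotype: bool = False):
        self.kg = kg
        self.path_cutoff = path_cutoff
        self.exclude_phenotype = exclude_phenotype

    def fit(self, X=None, y=None):
        if self.kg is None:
            raise ValueError("PathFeaturizer requires a knowledge graph")
        return self

    def transform(self, X: Iterable[Tuple[str, str]]
                  ) -> List[GenePairPathIndex]:
        self.fit()
        excluded = set(DEFAULT_EXCLUDED_NODE_TYPES)
        if self.exclude_phenotype:
            excluded.add("Phenotype")
        return featurize_pairs(self.kg, X, path_cutoff=self.path_cutoff,
                               excluded_node_types=excluded)


class DecisionSetClassifier(ClassifierMixin, BaseEstimator):
    """Interpretable rule-based classifier of gene-pair pathogenicity.

    ``fit`` takes a sequence of per-pair path indexes (from
    :class:`PathFeaturizer`), binary labels (1 = disease-causing) and
    optional per-pair confidence weights.  Mining runs on the positive
    class only; negatives enter through rule probabilities and set-cover
    selection.

    Attributes
    ----------
    model_ : DecisionSetModel
        selected rules with probabilities and the default negative
        probability.
    rules_ : list of Rule
        the selected rules.
    mined_rules_ : list of Rule
        all candidate rules after closedness filtering and threshold
        optimization.
    """

    def __init__(
        self,
        minsup_ratio: float = 0.2,
        max_rule_length: int = 3,
        alpha: float = 0.5,
        unification: bool = True,
        optimize: bool = True,
        de_popsize: int = 50,
        de_maxiter: int = 1000,
        de_recombination: float = 0.7,
        de_mutation: Tuple[float, float] = (0.5, 1.0),
        de_stagnation: int = 50,
        random_state: Optional[int] = None,
    ):
        self.minsup_ratio = minsup_ratio
        self.max_rule_length = max_rule_length
        self.alpha = alpha
        self.unification = unification
        self.optimize = optimize
        self.de_popsize = de_popsize
        self.de_maxiter = de_maxiter
        self.de_recombination = de_recombination
        self.de_mutation = de_mutation
        self.de_stagnation = de_stagnation
        self.random_state = random_state

    # -- helpers -------------------------------------------------------
    def _transactions(self, X, y, sample_weight):
        y = np.asarray(y)
        w = (np.ones(len(y)) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        D, N = [], []
        for i, (index, label) in enumerate(zip(X, y)):
            t = Transaction.from_index(f"pair{i}", float(w[i]), index)
            (D if label == self.classes_[1] else N).append(t)
        return D, N

    # -- sklearn API ---------------------------------------------------
    def fit(self, X: Sequence[GenePairPathIndex], y,
            sample_weight: Optional[Sequence[float]] = None):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        D, N = self._transactions(X, y, sample_weight)
        if not D or not N:
            raise ValueError("both classes must be non-empty")

        itemsets = apriori_mine(D, minsup_ratio=self.minsup_ratio,
                                max_rule_length=self.max_rule_length)
        candidates: List[Rule] = []
        for items, support in itemsets:
            rule = rule_from_itemset(items)
            rule.support = support
            candidates.append(rule)
        if self.unification:
            candidates.extend(
                extend_with_unifications(itemsets, D,
                                         minsup_ratio=self.minsup_ratio))
        candidates = closed_only(candidates)
        candidates.sort(key=Rule.sort_key)

        if self.optimize:
            rng = np.random.default_rng(self.random_state)
            refined = []
            for rule in candidates:
                ctx = FitnessContext(rule, D, minsup_ratio=self.minsup_ratio)
                theta, _ = optimize_thresholds(
                    rule, ctx, seed=int(rng.integers(0, 2**31 - 1)),
                    popsize=self.de_popsize, maxiter=self.de_maxiter,
                    recombination=self.de_recombination,
                    mutation=self.de_mutation,
                    stagnation_generations=self.de_stagnation,
                )
                r = rule.with_thetas(theta)
                r.support = ctx.coverage(theta) / ctx.total_weight
                refined.append(r)
            candidates = refined

        for rule in candidates:
            rule.confidence = rule_confidence(rule, D, N)
        self.mined_rules_ = candidates
        self.model_ = train_decision_set(
            candidates, D, N, alpha=self.alpha,
            metadata={
                "minsup_ratio": self.minsup_ratio,
                "max_rule_length": self.max_rule_length,
                "alpha": self.alpha,
                "n_positive": len(D),
                "n_negative": len(N),
                "random_state": self.random_state,
            },
        )
        self.rules_ = self.model_.rules
        self.default_negative_probability_ = self.model_.default_negative
        return self

    def predict_proba(self, X: Sequence[GenePairPathIndex]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        probs = np.array([self.model_.predict(index)[0] for index in X])
        return np.column_stack([1.0 - probs, probs])

    def predict(self, X: Sequence[GenePairPathIndex]) -> np.ndarray:
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba >= 0.5, self.classes_[1], self.classes_[0])

    def matched_rules(self, index: GenePairPathIndex) -> List[Rule]:
        """Rules matching one pair, ranked by probability (explanations)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return self.model_.predict(index)[1]
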
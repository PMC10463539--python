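"""Model evaluation: stratified cross-validation with per-fold retraining,
vertically averaged ROC/PR curves, geometric-mean threshold selection, a
random-walk-with-restart topological baseline, metapath-influence
statistics, and pair-connectivity ratios over graph components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import mannwhitneyu
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)
from sklearn.model_selection import StratifiedKFold

from .graph import KnowledgeGraph
from .paths import DEFAULT_EXCLUDED_NODE_TYPES, GenePairPathIndex
from .rules import Rule

__all__ = [
    "FoldResult",
    "stratified_cv",
    "average_curves",
    "optimal_threshold",
    "rwr_baseline",
    "metapath_influence",
    "connectivity_ratio",
]


@dataclass
class FoldResult:
    fold: int
    y_true: np.ndarray
    y_score: np.ndarray
    weights: np.ndarray
    auroc: float = field(init=False)
    auprc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auroc = float(roc_auc_score(self.y_true, self.y_score,
                                         sample_weight=self.weights))
        self.auprc = float(average_precision_score(
            self.y_true, self.y_score, sample_weight=self.weights))

    def roc_points(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return roc_curve(self.y_true, self.y_score,
                         sample_weight=self.weights)

    def pr_points(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return precision_recall_curve(self.y_true, self.y_score,
                                      sample_weight=self.weights)


def stratified_cv(
    indexes: Sequence[GenePairPathIndex],
    y: Sequence[int],
    sample_weight: Optional[Sequence[float]] = None,
    k: int = 10,
    seed: Optional[int] = 0,
    classifier=None,
    **classifier_params,
) -> List[FoldResult]:
    """Stratified k-fold evaluation with full retraining per fold.

    Rule mining, threshold optimization and decision-set selection run on
    the training fold only; the held-out fold is scored with the fold's
    model, so no test pair influences the rules applied to it.
    """
    from .estimators import DecisionSetClassifier

    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    w = (np.ones(len(y)) if sample_weight is None
         else np.asarray(sample_weight, dtype=float))
    indexes = list(indexes)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: List[FoldResult] = []
    for fi, (train, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        if classifier is not None:
            from sklearn.base import clone

            clf = clone(classifier)
        else:
            clf = DecisionSetClassifier(random_state=seed,
                                        **classifier_params)
        clf.fit([indexes[i] for i in train], y[train],
                sample_weight=w[train])
        scores = clf.predict_proba([indexes[i] for i in test])[:, 1]
        folds.append(FoldResult(fi, y[test], scores, w[test]))
    return folds


def average_curves(folds: Sequence[FoldResult], n_grid: int = 101) -> Dict:
    """Vertical averaging of the fold ROC and PR curves on a fixed grid.

    ROC curves are interpolated on an FPR grid, PR curves on a recall grid;
    the mean curve's area (trapezoid) is reported together with the
    per-fold AUROC/AUPRC mean and standard deviation.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs, precs = [], []
    for f in folds:
        fpr, tpr, _ = f.roc_points()
        tprs.append(np.interp(grid, fpr, tpr))
        prec, rec, _ = f.pr_points()
        order = np.argsort(rec)
        precs.append(np.interp(grid, rec[order], prec[order]))
    tprs = np.asarray(tprs)
    precs = np.asarray(precs)
    aurocs = np.array([f.auroc for f in folds])
    auprcs = np.array([f.auprc for f in folds])
    return {
        "grid": grid,
        "mean_tpr": tprs.mean(axis=0),
        "std_tpr": tprs.std(axis=0),
        "mean_precision": precs.mean(axis=0),
        "std_precision": precs.std(axis=0),
        "auroc_mean_curve": float(np.trapezoid(tprs.mean(axis=0), grid)),
        "auprc_mean_curve": float(np.trapezoid(precs.mean(axis=0), grid)),
        "auroc_mean": float(aurocs.mean()),
        "auroc_std": float(aurocs.std()),
        "auprc_mean": float(auprcs.mean()),
        "auprc_std": float(auprcs.std()),
    }


def optimal_threshold(fpr: np.ndarray, tpr: np.ndarray,
                      thresholds: np.ndarray) -> Tuple[float, float]:
    """Threshold maximizing the geometric mean of sensitivity and
    specificity, sqrt(tpr * (1 - fpr)); returns (threshold, gmean)."""
    gmean = np.sqrt(np.clip(tpr, 0, 1) * np.clip(1.0 - fpr, 0, 1))
    best = int(np.argmax(gmean))
    return float(thresholds[best]), float(gmean[best])


def rwr_baseline(
    kg: KnowledgeGraph,
    pair: Tuple[str, str],
    restart: float = 0.7,
    excluded_node_types: Iterable[str] = DEFAULT_EXCLUDED_NODE_TYPES,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> float:
    """Random walk with restart association score between two genes.

    The walk runs on the direction-agnostic graph minus the excluded node
    types, with uniform transition over incident edges; the score is the
    stationary probability of one gene when restarting at the other,
    averaged over both directions.  Disconnected pairs score 0.
    """
    excluded = set(excluded_node_types)
    nodes = [u for u, n in kg.nodes.items()
             if n.node_type not in excluded or u in pair]
    idx = {u: i for i, u in enumerate(nodes)}
    rows, cols = [], []
    for e in kg.edges:
        if e.source in idx and e.target in idx and e.source != e.target:
            rows.append(idx[e.source]); cols.append(idx[e.target])
            rows.append(idx[e.target]); cols.append(idx[e.source])
    n = len(nodes)
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()

    def walk(src: str, tgt: str) -> float:
        if src not in idx or tgt not in idx:
            return 0.0
        s = idx[src]
        e = np.zeros(n)
        e[s] = 1.0
        p = e.copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        # column-stochastic transition; dangling mass returns to the seed
        trans = adj.multiply(inv_deg[:, None]).tocsc().T.tocsr()
        dangling = deg == 0
        for _ in range(max_iter):
            spread = trans @ p
            spread[s] += p[dangling].sum()
            new = restart * e + (1.0 - restart) * spread
            if np.abs(new - p).sum() < tol:
                p = new
                break
            p = new
        return float(p[idx[tgt]])

    return 0.5 * (walk(pair[0], pair[1]) + walk(pair[1], pair[0]))


def metapath_influence(rules: Sequence[Rule], max_adj_p: float = 0.01
                       ) -> pd.DataFrame:
    """Metapaths significantly associated with higher rule confidence.

    For each metapath present in some but not all rules, the confidences of
    rules containing it are compared against those of rules lacking it with
    a one-tailed (greater) Wilcoxon rank-sum test; p-values are Bonferroni
    corrected over the tested metapaths and only metapaths with adjusted
    p <= ``max_adj_p`` are reported, ranked by rank-biserial correlation.
    """
    if len(rules) < 2:
        raise ValueError("need at least two rules")
    confidences = np.array([r.confidence for r in rules])
    universe = sorted({mp for r in rules for mp in r.metapaths},
                      key=lambda m: m.sort_key())
    rows = []
    tested = 0
    for mp in universe:
        has = np.array([mp in r.items for r in rules])
        if has.all() or not has.any():
            continue
        tested += 1
        x, yv = confidences[has], confidences[~has]
        stat, p = mannwhitneyu(x, yv, alternative="greater")
        rank_biserial = 2.0 * stat / (len(x) * len(yv)) - 1.0
        rows.append({"metapath": mp.abbreviation, "p_value": p,
                     "rank_biserial": rank_biserial,
                     "n_with": int(has.sum()), "n_without": int((~has).sum())})
    df = pd.DataFrame(rows, columns=["metapath", "p_value", "rank_biserial",
                                     "n_with", "n_without"])
    if df.empty:
        df["adj_p"] = []
        return df
    df["adj_p"] = np.minimum(df["p_value"] * tested, 1.0)
    df = df[df["adj_p"] <= max_adj_p]
    return df.sort_values("rank_biserial", ascending=False).reset_index(
        drop=True)


def connectivity_ratio(
    kg: KnowledgeGraph,
    pairs: Sequence[Tuple[str, str]],
    metaedge_subset: Optional[Iterable[str]] = None,
    cutoffs: Sequence[int] = (1, 2, 3, 4),
    excluded_node_types: Iterable[str] = DEFAULT_EXCLUDED_NODE_TYPES,
) -> pd.DataFrame:
    """Fraction of gene pairs with at least one path within each cutoff,
    ignoring direction, restricted to a metaedge subset and avoiding the
    excluded node types as intermediates."""
    allowed = None if metaedge_subset is None else set(metaedge_subset)
    excluded = set(excluded_node_types)
    max_cut = max(cutoffs)
    dists = []
    for src, tgt in pairs:
        dists.append(_pair_distance(kg, src, tgt, max_cut, allowed, excluded))
    rows = [
        {"cutoff": c,
         "ratio": float(np.mean([d is not None and d <= c for d in dists]))
         if pairs else 0.0}
        for c in cutoffs
    ]
    return pd.DataFrame(rows)


def _pair_distance(kg, src, tgt, max_cut, allowed, excluded):
    if src not in kg.nodes or tgt not in kg.nodes:
        return None
    frontier = {src}
    seen = {src}
    for depth in range(1, max_cut + 1):
        nxt = set()
        for u in frontier:
            for edge, other, _ in kg.adjacency(u):
                if allowed is not None and edge.metaedge not in allowed:
                    continue
                if other == tgt:
                    return depth
                if other in seen:
                    continue
                if kg.nodes[other].node_type in excluded:
                    continue
                seen.add(other)
                nxt.add(other)
        frontier = nxt
        if not frontier:
            break
    return None
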
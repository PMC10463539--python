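"""Per-rule path-reliability threshold refinement.

Each rule condition gets a threshold theta in [0, 1]; paths scoring below it
no longer count towards the condition.  Raising thresholds prunes noisy,
low-reliability paths (improving interpretability) but can shrink the
rule's positive coverage, so the two are traded off by the fitness

    f(r, Theta) = 1/2 * ( |C_{r|Theta}(D)| / |C_r(D)|
                          + (1 - Pbar_{r|Theta}(D) / Pbar_r(D)) )

where C is weighted positive coverage and Pbar the weighted mean number of
qualifying paths over covered pairs; f = 0 whenever coverage at Theta falls
below the mining minimum support.  The search uses differential evolution
(DE/best/1/bin) with the zero vector injected into the initial population,
so the unthresholded rule (f = 0.5) is always a feasible incumbent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import differential_evolution

from .rules import Rule, Transaction, qualifying_paths

__all__ = ["FitnessContext", "mean_paths", "fitness", "optimize_thresholds",
           "optimize_rule", "DEFAULT_DE_PARAMS"]

DEFAULT_DE_PARAMS = {
    "popsize": 50,
    "maxiter": 1000,
    "recombination": 0.7,
    "mutation": (0.5, 1.0),
    "stagnation_generations": 50,
    "stagnation_tol": 1e-6,
}

_EPS = 1e-12


class FitnessContext:
    """Pre-indexed per-rule path data for fast fitness evaluation.

    Baselines (coverage and mean path count) are computed at Theta = 0 over
    the positive set D; only transactions covered at Theta = 0 can be
    covered at any Theta, so per-path reliability arrays are kept for those.
    """

    def __init__(self, rule: Rule, D: Sequence[Transaction],
                 minsup_ratio: float = 0.2) -> None:
        self.rule = rule
        self.minsup_ratio = minsup_ratio
        self.n_conditions = len(rule.conditions)
        self.total_weight = float(sum(t.weight for t in D))
        if self.total_weight <= 0:
            raise ValueError("positive set carries no weight")

        u = rule.unification
        covered: List[Transaction] = []
        per_cond_rel: List[List[float]] = [[] for _ in range(self.n_conditions)]
        per_cond_txn: List[List[int]] = [[] for _ in range(self.n_conditions)]
        per_cond_mate: List[List[float]] = [[] for _ in range(self.n_conditions)]
        node_txn: List[int] = []
        node_mi: List[float] = []
        node_mj: List[float] = []
        maxima: List[List[float]] = []
        weights: List[float] = []
        path_total = 0.0

        for t in D:
            qp = qualifying_paths(rule, t.index)
            if qp is None:
                continue
            ti = len(covered)
            covered.append(t)
            weights.append(t.weight)
            row = []
            n_paths = 0
            if u is not None:
                # per shared node: best reliability on each unified condition
                best_i = {}
                best_j = {}
                for p in qp[u.i]:
                    x = p.node_uris[u.position_i]
                    best_i[x] = max(best_i.get(x, 0.0), p.reliability)
                for p in qp[u.j]:
                    x = p.node_uris[u.position_j]
                    best_j[x] = max(best_j.get(x, 0.0), p.reliability)
                for x in set(best_i) & set(best_j):
                    node_txn.append(ti)
                    node_mi.append(best_i[x])
                    node_mj.append(best_j[x])
                for ci, paths in qp.items():
                    row.append(max(p.reliability for p in paths))
                    for p in paths:
                        per_cond_rel[ci].append(p.reliability)
                        per_cond_txn[ci].append(ti)
                        if ci == u.i:
                            per_cond_mate[ci].append(
                                best_j.get(p.node_uris[u.position_i], 0.0))
                        elif ci == u.j:
                            per_cond_mate[ci].append(
                                best_i.get(p.node_uris[u.position_j], 0.0))
                        else:
                            per_cond_mate[ci].append(np.inf)
                        n_paths += 1
            else:
                for ci, paths in qp.items():
                    row.append(max(p.reliability for p in paths))
                    for p in paths:
                        per_cond_rel[ci].append(p.reliability)
                        per_cond_txn[ci].append(ti)
                        per_cond_mate[ci].append(np.inf)
                        n_paths += 1
            maxima.append(row)
            path_total += t.weight * n_paths

        self.n_covered0 = len(covered)
        self.weights = np.asarray(weights, dtype=float)
        self.cov0_weight = float(self.weights.sum()) if len(weights) else 0.0
        self.maxima = (np.asarray(maxima, dtype=float)
                       if covered else np.zeros((0, self.n_conditions)))
        self.rel = [np.asarray(a, dtype=float) for a in per_cond_rel]
        self.txn = [np.asarray(a, dtype=int) for a in per_cond_txn]
        self.mate = [np.asarray(a, dtype=float) for a in per_cond_mate]
        self.node_txn = np.asarray(node_txn, dtype=int)
        self.node_mi = np.asarray(node_mi, dtype=float)
        self.node_mj = np.asarray(node_mj, dtype=float)
        self.mean_paths0 = (path_total / self.cov0_weight
                            if self.cov0_weight > 0 else 0.0)

    # -- evaluation ---------------------------------------------------
    def _covered_mask(self, theta: np.ndarray) -> np.ndarray:
        if self.n_covered0 == 0:
            return np.zeros(0, dtype=bool)
        mask = np.all(self.maxima >= theta[None, :] - _EPS, axis=1)
        u = self.rule.unification
        if u is not None and self.node_txn.size:
            ok = (self.node_mi >= theta[u.i] - _EPS) & \
                 (self.node_mj >= theta[u.j] - _EPS)
            has_shared = np.zeros(self.n_covered0, dtype=bool)
            np.logical_or.at(has_shared, self.node_txn[ok], True)
            mask &= has_shared
        elif u is not None:
            mask &= False
        return mask

    def _path_counts(self, theta: np.ndarray) -> np.ndarray:
        counts = np.zeros(self.n_covered0)
        u = self.rule.unification
        for ci in range(self.n_conditions):
            qual = self.rel[ci] >= theta[ci] - _EPS
            if u is not None and ci == u.i:
                qual &= self.mate[ci] >= theta[u.j] - _EPS
            elif u is not None and ci == u.j:
                qual &= self.mate[ci] >= theta[u.i] - _EPS
            counts += np.bincount(self.txn[ci][qual],
                                  minlength=self.n_covered0)
        return counts

    def coverage(self, theta: Sequence[float]) -> float:
        """Weighted positive coverage |C_{r|Theta}(D)|."""
        mask = self._covered_mask(np.asarray(theta, dtype=float))
        return float(self.weights[mask].sum())

    def mean_paths(self, theta: Sequence[float]) -> float:
        """Weighted mean qualifying-path count over covered positives."""
        theta = np.asarray(theta, dtype=float)
        mask = self._covered_mask(theta)
        cov = float(self.weights[mask].sum())
        if cov <= 0:
            raise ValueError("no instance covered at this threshold vector")
        counts = self._path_counts(theta)
        return float((self.weights[mask] * counts[mask]).sum() / cov)

    def fitness(self, theta: Sequence[float]) -> float:
        theta = np.asarray(theta, dtype=float)
        mask = self._covered_mask(theta)
        cov = float(self.weights[mask].sum())
        if cov / self.total_weight < self.minsup_ratio - _EPS:
            return 0.0
        if self.cov0_weight <= 0 or self.mean_paths0 <= 0:
            return 0.0
        counts = self._path_counts(theta)
        mean_p = float((self.weights[mask] * counts[mask]).sum() / cov)
        return 0.5 * (cov / self.cov0_weight + (1.0 - mean_p / self.mean_paths0))


def mean_paths(rule: Rule, theta: Sequence[float],
               D: Sequence[Transaction]) -> float:
    return FitnessContext(rule, D, minsup_ratio=0.0).mean_paths(theta)


def fitness(rule: Rule, theta: Sequence[float],
            context: FitnessContext) -> float:
    return context.fitness(theta)


def optimize_thresholds(
    rule: Rule,
    context: FitnessContext,
    seed: Optional[int] = None,
    popsize: int = 50,
    maxiter: int = 1000,
    recombination: float = 0.7,
    mutation: Tuple[float, float] = (0.5, 1.0),
    stagnation_generations: int = 50,
    stagnation_tol: float = 1e-6,
) -> Tuple[np.ndarray, float]:
    """Best threshold vector found by DE/best/1/bin within the budget.

    The zero vector is part of the initial population, so the returned
    fitness is never below f(Theta = 0); the search stops early after
    ``stagnation_generations`` generations without improvement.
    """
    k = len(rule.conditions)
    rng = np.random.default_rng(seed)
    init = rng.uniform(0.0, 1.0, size=(max(popsize, 5), k))
    init[0, :] = 0.0

    def objective(x: np.ndarray) -> float:
        return -context.fitness(x)

    best_seen = {"val": np.inf, "stale": 0}

    def callback(xk, convergence=0.0):  # noqa: ANN001 - scipy signature
        val = objective(np.asarray(xk, dtype=float))
        if val < best_seen["val"] - stagnation_tol:
            best_seen["val"] = val
            best_seen["stale"] = 0
        else:
            best_seen["stale"] += 1
        return best_seen["stale"] >= stagnation_generations

    result = differential_evolution(
        objective,
        bounds=[(0.0, 1.0)] * k,
        strategy="best1bin",
        init=init,
        maxiter=maxiter,
        mutation=mutation,
        recombination=recombination,
        tol=0.0,
        polish=False,
        seed=int(rng.integers(0, 2**31 - 1)),
        callback=callback,
    )
    theta = np.clip(np.asarray(result.x, dtype=float), 0.0, 1.0)
    fit = context.fitness(theta)
    zero_fit = context.fitness(np.zeros(k))
    if zero_fit > fit:  # never regress below the feasible incumbent
        theta, fit = np.zeros(k), zero_fit
    return theta, fit


def optimize_rule(rule: Rule, D: Sequence[Transaction],
                  minsup_ratio: float = 0.2, seed: Optional[int] = None,
                  **de_params) -> Rule:
    """Convenience wrapper: returns the rule with optimized thresholds and
    its support refreshed at those thresholds."""
    context = FitnessContext(rule, D, minsup_ratio=minsup_ratio)
    theta, _ = optimize_thresholds(rule, context, seed=seed, **de_params)
    refined = rule.with_thetas(theta)
    refined.support = context.coverage(theta) / context.total_weight
    refined.confidence = rule.confidence
    return refined
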
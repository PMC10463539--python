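"""Construction of weighted positive / negative gene-pair training sets.

Positives come from curated oligogenic variant-combination records: two-gene
combinations at or above a minimum evidence level, aggregated per gene pair
with the maximum evidence weight.  A held-out test set is drawn from the
most recently published, at-least-moderate-evidence, gene-disjoint pairs.
Negatives are frequent co-occurring gene pairs in healthy individuals whose
variant deleteriousness profile resembles the pathogenic pairs, ranked by a
carrier-averaged score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "OligoRecord",
    "VariantRecord",
    "LabeledGenePair",
    "EVIDENCE_LEVELS",
    "DEFAULT_LEVEL_WEIGHTS",
    "aggregate_positive",
    "select_holdout",
    "build_negative",
    "assign_weights",
]

EVIDENCE_LEVELS = ("weak", "moderate", "strong")
DEFAULT_LEVEL_WEIGHTS: Dict[str, float] = {
    "weak": 0.25, "moderate": 0.5, "strong": 1.0
}


@dataclass(frozen=True)
class OligoRecord:
    combination_id: str
    genes: FrozenSet[str]
    evidence_level: str
    publication_date: str  # ISO date, lexicographically ordered
    disease_id: str = ""

    def __post_init__(self) -> None:
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise ValueError(
                f"evidence level must be one of {EVIDENCE_LEVELS}, "
                f"got {self.evidence_level!r}"
            )


@dataclass(frozen=True)
class VariantRecord:
    individual_id: str
    gene_id: str
    chromosome: str
    position: int
    maf: float
    score: float  # deleteriousness (CADD-scale)

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 1.0):
            raise ValueError("MAF must lie in [0, 1]")


@dataclass(frozen=True)
class LabeledGenePair:
    genes: Tuple[str, str]
    label: str  # "disease-causing" or "neutral"
    weight: float

    def __post_init__(self) -> None:
        if self.genes[0] == self.genes[1]:
            raise ValueError("pair genes must be distinct")
        if not (self.weight > 0):
            raise ValueError("weight must be > 0")


def aggregate_positive(
    records: Iterable[OligoRecord],
    min_level: str = "weak",
    level_weights: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Aggregate two-gene combinations into one row per gene pair.

    Returns a DataFrame (gene_a, gene_b, weight, evidence_level,
    first_date) where the weight and level are the maximum over the
    contributing records and first_date is the earliest publication date.
    Gene order within a pair is lexicographic.
    """
    weights = dict(level_weights or DEFAULT_LEVEL_WEIGHTS)
    min_rank = EVIDENCE_LEVELS.index(min_level)
    agg: Dict[Tuple[str, str], Dict] = {}
    for r in records:
        if len(r.genes) != 2:
            continue
        if EVIDENCE_LEVELS.index(r.evidence_level) < min_rank:
            continue
        pair = tuple(sorted(r.genes))
        cur = agg.get(pair)
        rank = EVIDENCE_LEVELS.index(r.evidence_level)
        if cur is None:
            agg[pair] = {"rank": rank, "first_date": r.publication_date}
        else:
            cur["rank"] = max(cur["rank"], rank)
            cur["first_date"] = min(cur["first_date"], r.publication_date)
    rows = [
        {
            "gene_a": a,
            "gene_b": b,
            "weight": weights[EVIDENCE_LEVELS[v["rank"]]],
            "evidence_level": EVIDENCE_LEVELS[v["rank"]],
            "first_date": v["first_date"],
        }
        for (a, b), v in sorted(agg.items())
    ]
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "weight", "evidence_level",
                       "first_date"]
    )


def select_holdout(pairs: pd.DataFrame, k: int = 15
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pick up to ``k`` held-out test pairs: scanning from the most recent
    first-publication date, accept pairs of at least moderate evidence whose
    genes do not overlap any previously accepted pair."""
    order = pairs.sort_values(
        ["first_date", "gene_a", "gene_b"], ascending=[False, True, True]
    )
    used_genes: set = set()
    chosen: List[int] = []
    for idx, row in order.iterrows():
        if len(chosen) >= k:
            break
        if EVIDENCE_LEVELS.index(row["evidence_level"]) < 1:  # < moderate
            continue
        if row["gene_a"] in used_genes or row["gene_b"] in used_genes:
            continue
        chosen.append(idx)
        used_genes |= {row["gene_a"], row["gene_b"]}
    test = pairs.loc[chosen]
    rest = pairs.drop(index=chosen)
    return test, rest


def build_negative(
    variants: Iterable[VariantRecord],
    gene_coords: Optional[pd.DataFrame] = None,
    max_maf: float = 0.03,
    min_carriers: int = 50,
    min_pair_score: float = 3.57,
    min_distance_bp: int = 10_000,
    target_ratio: int = 100,
    n_positive: Optional[int] = None,
) -> pd.DataFrame:
    """Derive ranked putative-neutral gene pairs from healthy-cohort
    variants.

    Pipeline: MAF filter -> per-individual per-gene maximum score ->
    per-individual pair generation -> carrier-count filter -> pair maximum
    score filter (> ``min_pair_score``) -> genomic separation filter
    (different chromosomes, or closest gene boundaries >=
    ``min_distance_bp`` apart; requires ``gene_coords`` with columns
    gene, chromosome, start, end) -> pair score = carrier mean of the
    per-carrier minimum gene score -> descending rank, truncated to
    ``target_ratio * n_positive`` when ``n_positive`` is given.

    Returns a DataFrame (gene_a, gene_b, n_carriers, score, weight).
    """
    df = pd.DataFrame([r.__dict__ for r in variants])
    if df.empty:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "n_carriers", "score", "weight"]
        )
    df = df[df["maf"] <= max_maf]
    # per-individual per-gene max deleteriousness
    gene_scores = (
        df.groupby(["individual_id", "gene_id"])["score"].max().reset_index()
    )
    # per-individual gene pairs
    pair_rows = []
    for ind, sub in gene_scores.groupby("individual_id"):
        genes = sub.sort_values("gene_id")
        recs = list(genes.itertuples(index=False))
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                pair_rows.append(
                    {
                        "gene_a": a.gene_id,
                        "gene_b": b.gene_id,
                        "min_score": min(a.score, b.score),
                        "max_score": max(a.score, b.score),
                    }
                )
    if not pair_rows:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "n_carriers", "score", "weight"]
        )
    pairs = pd.DataFrame(pair_rows)
    stats = pairs.groupby(["gene_a", "gene_b"]).agg(
        n_carriers=("min_score", "size"),
        score=("min_score", "mean"),
        max_score=("max_score", "max"),
    ).reset_index()
    stats = stats[stats["n_carriers"] >= min_carriers]
    stats = stats[stats["max_score"] > min_pair_score]
    if gene_coords is not None and not stats.empty:
        coords = gene_coords.set_index("gene")
        keep = []
        for row in stats.itertuples(index=False):
            ca = coords.loc[row.gene_a]
            cb = coords.loc[row.gene_b]
            if ca["chromosome"] != cb["chromosome"]:
                keep.append(True)
            else:
                gap = max(ca["start"], cb["start"]) - min(ca["end"], cb["end"])
                keep.append(gap >= min_distance_bp)
        stats = stats[np.asarray(keep, dtype=bool)]
    stats = stats.sort_values(
        ["score", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if n_positive is not None:
        stats = stats.head(target_ratio * n_positive)
    stats = stats.drop(columns=["max_score"])
    stats["weight"] = assign_weights(stats["score"].to_numpy())
    return stats


def assign_weights(scores: Sequence[float], floor: float = 0.1) -> np.ndarray:
    """Monotone min-max map of scores onto (0, 1], with a floor so that the
    lowest-scoring pair still carries weight.  Constant scores map to 1."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return scores
    lo, hi = scores.min(), scores.max()
    if hi - lo <= 0:
        return np.ones_like(scores)
    return floor + (1.0 - floor) * (scores - lo) / (hi - lo)
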
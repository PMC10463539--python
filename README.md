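# pathrules

Interpretable prediction of disease-causing (pathogenic) gene pairs from
heterogeneous paths in a typed biological knowledge graph, with subgraph
explanations for every positive prediction.

## The problem

Oligogenic diseases are caused by the combined effect of variants in two or
a few genes (digenic = exactly two). Statistical predictors of pathogenic
gene pairs exist, but they rely on abstract features and black-box models
that clinicians cannot audit. `pathrules` takes the opposite route: it
reasons over *paths* in a knowledge graph that integrates gene-centric
networks (physical interaction, co-expression, sequence similarity) with
functional annotations (GO terms, phenotypes, protein domains, families,
complexes), and learns a small set of human-readable rules whose firing can
be traced back to concrete entities and relationships.

## The model

For a gene pair (ordered by the Residual Variation Intolerance Score, RVIS),
all simple paths of length ≤ `path_cutoff` (default 3) between the two
genes are enumerated, skipping Disease and OligogenicCombination nodes
(which inherently contain the answer). Each path gets a **reliability**
score — the geometric mean of its edge confidence scores — and is
aggregated into its **metapath**: the sequence of node types, edge types
and traversal directions (e.g. `GaBPaG` = both genes associated with the
same BiologicalProcess).

Training proceeds in four stages:

1. **Rule mining.** Frequent metapath itemsets are mined from the
   pathogenic pairs D only (weighted Apriori, relative support ≥
   `minsup_ratio` = 0.2, at most `max_rule_length` = 3 conditions), kept
   only if *closed* (no strict super-pattern of equal support), and
   optionally extended with a single **unification** constraint — paths of
   two conditions must share an intermediate node (e.g. BP₁ = BP₂).
2. **Threshold refinement.** Each rule condition gets a reliability
   threshold θ ∈ [0, 1] chosen by differential evolution (DE/best/1/bin,
   population 50, ≤ 1000 generations, recombination 0.7, mutation dithered
   in [0.5, 1]) maximizing
   `f(r, Θ) = ½(|C_{r|Θ}(D)|/|C_r(D)| + 1 − P̄_{r|Θ}(D)/P̄_r(D))`,
   i.e. keep coverage, prune noisy paths; `f = 0` below minimum support.
3. **Decision-set selection.** Greedy weighted set cover minimizes
   `w(R) = α(1 − |C_R(D)|/|D|) + (1 − α)|C_R(N)|/|N|` (α = 0.5) against the
   neutral pairs N, adding the rule of minimum marginal weight until no
   rule decreases w.
4. **Calibration.** Each selected rule carries the imbalance-corrected
   precision `p(l_D|r) = |C_r(D)| / (|C_r(D)| + (|D|/|N|)|C_r(N)|)`;
   prediction returns the highest-probability matching rule, or a default
   negative probability estimated from uncovered training pairs.

All coverages are weighted by per-pair label confidence. Every positive
prediction can be *explained*: each matched rule is turned into a graph
query returning exactly the paths that satisfy it, exported as GraphML.

## Worked example

```python
import numpy as np
import pathrules as pr

# synthetic knowledge graph with three planted patterns (one unified)
data = pr.generate(pr.SimulationConfig(seed=1))
pairs = [(a, b) for a, b, _ in data.positive_pairs + data.negative_pairs]
X = pr.featurize_pairs(data.kg, pairs)             # path indexes
y = np.r_[np.ones(60), np.zeros(600)]
w = np.r_[[p[2] for p in data.positive_pairs],
          [n[2] for n in data.negative_pairs]]

clf = pr.DecisionSetClassifier(random_state=1).fit(X, y, sample_weight=w)
for r in clf.rules_:
    print(f"{r.to_text():60s} p={r.probability:.3f}")
prob, explanations = pr.explain_pair(clf.model_, X[0])
print(f"pair {X[0].pair}: P(pathogenic) = {prob:.3f}")
```

prints (seed 1):

```
GaBPaG >= 0.79 & GaMFaG >= 0.66 & GpG >= 0.47                p=0.996
GaBPaG >= 0.25 & GaBPaGeG >= 0.24 & GaBPaGpG >= 0.71 | BP1=BP2 p=0.963
pair ('gene0146', 'gene0187'): P(pathogenic) = 0.963
```

The first rule reads: the pair shares a biological process via reliable
annotations (path reliability ≥ 0.79), shares a molecular function
(≥ 0.66), and physically interacts (≥ 0.47). The second requires the
shared biological process of the pair to be the *same* process (BP₁ = BP₂)
that a third, physically interacting gene participates in. The probability
is the imbalance-corrected precision of the best matching rule on training
data.

The same workflow is available from the shell:

```bash
pathrules simulate --out sim/ --seed 1
pathrules train sim/kg.graphml --positives sim/positives.tsv \
    --negatives sim/negatives.tsv --out model.json
pathrules predict sim/kg.graphml --model model.json --pairs sim/positives.tsv
pathrules explain sim/kg.graphml --model model.json --pair gene0146,gene0187 --out expl/
```

## Layout

- `src/pathrules/schema.py`, `graph.py` — the 10-metanode / 17-metaedge
  schema, GraphML/TSV readers and writers, validation.
- `scoring.py` — functional information (FI), SimGIC, BLAST score ratio,
  co-expression filtering, protein→gene collapsing.
- `paths.py` — path enumeration, tissue consistency, reliability.
- `rules.py`, `thresholds.py`, `decision_set.py` — mining, DE refinement,
  set-cover training.
- `estimators.py` — sklearn-compatible `PathFeaturizer` and
  `DecisionSetClassifier`.
- `datasets.py` — positive/negative pair construction from curated
  oligogenic records and healthy-cohort variant tables.
- `simulate.py` — the synthetic-graph generator.
- `explain.py`, `evaluate.py` — explanations, CV, curves, RWR baseline,
  metapath-influence statistics, connectivity ratios.
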
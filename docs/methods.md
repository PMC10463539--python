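# Methods

## Scope and model

`pathrules` implements an associative classifier over a typed biological
knowledge graph. The unit of prediction is an ordered gene pair; the
feature space is the set of *metapaths* — typed, directed path signatures —
realized between the two genes within a bounded number of hops. The
classifier is a decision set: an unordered collection of conjunctive rules,
each a set of metapath conditions with per-condition reliability
thresholds and at most one unification constraint, interpreted
disjunctively. This document records the modelling assumptions, parameter
choices and numerical decisions; design points that were genuinely open
are marked as such.

## Graph schema

Ten node types (Gene, Disease, Phenotype, BiologicalProcess,
MolecularFunction, CellularComponent, ProteinDomain, ProteinFamily,
ProteinComplex, OligogenicCombination) and seventeen edge types
(metaedges), each identified by an abbreviation such as `GaBP`
(Gene −associated→ BiologicalProcess). Seven metaedges are undirected
associations (`GeG`, `GpG`, `GsG`, `PrP`, `BPrBP`, `MFrMF`, `CCrCC`);
they are canonicalized with endpoints in lexicographic URI order, and
duplicate or reversed entries merge keeping the maximum score — the same
convention used when collapsing protein-level edges onto genes. Edge
scores, when present, are confidences in [0, 1]. Two nodes may carry at
most one edge per metaedge; parallel edges across distinct metaedges are
allowed. GraphML is the primary exchange format; an equivalent TSV
(Neo4j-import-style: header row, tab-separated, pipe-joined sets) reader
and writer round-trips identically, with a configurable column map since
tabular dialects vary.

## Edge scoring

- **Functional information.** A gene→annotation edge is scored
  `FI(t) = −log(|g(t ∪ subterms)|/|g(T)|) / log|g(T)|` — the information
  content of the term scaled into [0, 1]: 0 when the term annotates every
  gene of its ontology, 1 when it annotates a single gene. Natural
  logarithm; the base cancels in the ratio.
- **SimGIC** term-term similarity: IC sum over shared ancestors (terms
  inclusive) divided by IC sum over the ancestor union; `resembles` edges
  are emitted above 0.5.
- **BLAST score ratio**: cross bit score over the minimum of the two
  self-alignment scores, clamped at 1, computed only when the alignment
  covers ≥ 50 % of the shorter protein; `seqSimilar` edges require
  BSR ≥ 0.2. Using the *minimum* self-score keeps the ratio in [0, 1];
  the query-relative alternative does not, and the symmetric form was the
  open choice made here.
- **Tissue co-expression**: records are kept when the tissue has ≥ 70
  samples, neither gene is an expression outlier (z ≥ −3), the adjusted
  p-value is < 0.01, and the correlation clears ρ ≥ 0.80 after a Fisher
  sample-size adjustment. The adjustment implemented is
  `atanh(ρ) ≥ atanh(0.80) − z_crit/√(n−3)` with `z_crit = Φ⁻¹(0.99)`; the
  exact published adjustment rule is not specified, so this one-sided
  confidence margin is our reading, and both the threshold and alpha are
  parameters. Survivors are grouped per gene pair into one `GeG` edge
  scored by the maximum correlation, with the surviving tissues in the
  `in` property.
- **Phenotype frequency** classes on Disease→Phenotype edges map to the
  midpoints of their frequency ranges (Obligate = 1.0, Very frequent =
  0.895, …, Excluded = 0.0); no score when the class is missing. The
  published mapping is not printed anywhere, so midpoints are the neutral
  choice.

## Path enumeration

Paths are **simple** (no repeated node) — revisiting nodes creates
degenerate cycles and no worked example ever revisits one. Traversal
ignores edge direction but records it: each metapath step carries the
metaedge plus a forward flag, and the abbreviation renders left-to-right
from the source gene. The source is the gene with the **lower RVIS**; ties
break by lexicographic URI and missing RVIS sorts last, so ordering is
deterministic. Intermediate nodes of type Disease and
OligogenicCombination are never traversed (they encode the label);
Phenotype can additionally be excluded to avoid the annotation-coverage
bias of well-studied disease genes. Paths crossing two or more
co-expression edges with disjoint tissue sets are discarded; a `GeG` edge
lacking the `in` property is treated as tissue-universal (permissive
default). Path reliability is the geometric mean of edge scores, with
unscored edges contributing 1.0. The default cutoff of 3 edges is the
point at which integrated graphs connect essentially all pathogenic pairs.

## Rule mining

Transactions are the positive pairs; items are the metapaths with at least
one admissible path. Support is weighted — Σ covered weights / Σ all
weights — and an itemset is frequent at `minsup_ratio = 0.2` with at most
`max_rule_length = 3` conditions. The Apriori search is exact (verified
against exhaustive enumeration). Unification candidates are all pairs of
intermediate positions of equal node type across two different conditions;
a unified rule is kept if its support, evaluated through the full matcher
(shared-node existence), stays frequent, and a rule carries at most one
unification. Redundancy is removed by keeping **closed** patterns only: a
rule is dropped when a strict super-pattern (superset itemset with a
compatible unification, or the same itemset plus a unification) has equal
support within 1e−12. Ties and orderings everywhere use the lexicographic
metapath abbreviation, so mining is deterministic.

Rule confidence is operationalized as the imbalance-corrected precision
`|C_r(D)| / (|C_r(D)| + (|D|/|N|)·|C_r(N)|)` — the same quantity used as
the class probability — since no separate quantitative definition exists.

## Threshold refinement

For each rule, per-condition thresholds Θ are searched in [0, 1]^k by
differential evolution, DE/best/1/bin, population 50, up to 1000
generations, recombination 0.7, mutation dithered uniformly in [0.5, 1]
per generation (scipy's implementation). The fitness is
`½(|C_{r|Θ}(D)|/|C_r(D)| + 1 − P̄_{r|Θ}(D)/P̄_r(D))`, zero when support at
Θ falls below `minsup_ratio`. Both the coverage and the mean path count
P̄ are weighted by pair confidence (the printed mean-path formula is
unweighted, but the optimisation description states that weights adjust
both; we follow the weighted form throughout). For unified rules, a path
counts as qualifying when it clears its condition's threshold *and* passes
through a node consistent with the other unified condition at its
threshold — the union over joint assignments; this same definition is
shared by the matcher, the fitness and the explainer, so explanations are
sound by construction. Numerical choices: the zero vector is injected into
the initial population so the unthresholded rule (fitness 0.5 when
baseline support is feasible) is always an incumbent and the result never
regresses below it; the search stops early after 50 generations without
improvement beyond 1e−6; no polishing step (the objective is piecewise
constant, gradients are meaningless); threshold comparisons use a 1e−12
slack so a path exactly at the threshold qualifies.

## Decision-set training

Greedy weighted set cover with
`w(R) = α(1 − |C_R(D)|/|D|) + (1 − α)|C_R(N)|/|N|`, α = 0.5, all
quantities weighted; the rule of minimum marginal weight is added until no
rule strictly decreases w, so w(R) strictly decreases along the trace.
Ties break by higher rule probability, then lexicographic serialization.
Prediction returns the maximum probability among matching rules; a pair
matching nothing gets a default probability computed by applying the same
imbalance-corrected formula to the *uncovered* training remainder — the
published description says only "based on uncovered training instances",
and reusing one calibration convention keeps the probability scale
consistent.

## Training-set construction

Positives: two-gene combinations at ≥ weak evidence, aggregated per gene
pair with the maximum evidence weight (defaults weak = 0.25,
moderate = 0.5, strong = 1.0 — configurable, as the published mapping is
supplementary). A hold-out set scans pairs from the most recent first
publication date, accepting gene-disjoint pairs of ≥ moderate evidence up
to k = 15. Negatives: healthy-cohort variants with MAF ≤ 0.03 are
collapsed to a per-individual per-gene maximum deleteriousness score;
per-individual gene pairs are filtered to ≥ 50 carriers, pair maximum
score > 3.57 (a fixed quartile of the pathogenic distribution, configurable
rather than recomputed), and genomic separation (different chromosomes or
closest gene boundaries ≥ 10 kb apart — the anchor point was unspecified;
closest boundaries is the conservative reading). The pair score is the
carrier mean of the per-carrier minimum gene score; pairs are ranked
descending and truncated at 100 × |D|. Weights are a min-max map of the
score onto [0.1, 1] — any monotone map onto (0, 1] would do; the floor
keeps the lowest-ranked pair from vanishing from weighted support.

## Synthetic data

The generator emulates the study inputs at desk scale: a
schema-conformant graph whose background edges are drawn per metaedge by
uniform endpoint sampling with Beta(4, 2) confidence scores (right-skewed,
mean 2/3, resembling curated-network score distributions), genes carrying
standard-normal RVIS, co-expression edges carrying 1–3 of 5 tissues.
Defaults: 300 genes, ~1,900 background edges, 60 positive and 600 negative
pairs (1:10 — the full study imbalance of 1:100 at 441 positives is not
desk-scale; the ratio still makes negative coverage the binding
constraint), three planted patterns including one with a BP₁ = BP₂
unification, planted into positives with probability 0.9 and negatives
with 0.02, plant reliabilities uniform in [0.7, 1.0]. Planting is
constructive on the RVIS-ordered pair, so a planted pattern is guaranteed
to match. What the generator does *not* emulate: scale-free degree
structure, ontology hierarchy realism, annotation-coverage bias between
well- and poorly-studied genes, and linkage structure among negatives —
so passing recovery tests demonstrates correctness of the machinery, not
real-data performance.

## Evaluation

Stratified k-fold cross-validation re-runs mining, threshold refinement
and set-cover selection inside each training fold (mining once globally
would leak test pairs into the rules; the global variant is available by
training a single classifier). ROC and PR curves are averaged vertically
on a fixed 101-point grid (threshold-based averaging is the alternative;
vertical is what "averaging all fold curves" most naturally yields), with
the mean curve's trapezoid area and per-fold AUROC/AUPRC spread reported.
The operating point maximizes the geometric mean of sensitivity and
specificity. The topological baseline is a random walk with restart
(restart 0.7) on the direction-agnostic graph minus excluded node types,
uniform transition over incident edges (the cited technique's exact
normalization is unstated), dangling mass returned to the seed, iterated
to L1 1e−10, symmetrized by averaging both directions. Metapath influence
compares rule confidences with vs without each metapath by one-tailed
Wilcoxon rank-sum with Bonferroni correction, reporting rank-biserial
effect sizes.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
generator defaults above (660 pairs, ~2,400 edges after planting); oracle
comparisons use ≤ 30-node graphs, ≤ 50-transaction mining instances, and
0.01/0.02-step threshold grids. These sizes are the package's chosen
desk-scale study conditions; the pipeline itself has no size-dependent
switches.

## Known limitations

- Unified-rule path counts treat individual qualifying paths, not joint
  path tuples; if the original counts tuples, reported per-rule path
  numbers would differ for unified rules.
- The miner never mines from the neutral class, and supports only one
  unification per rule and pairwise unifications.
- Probabilities are not recalibrated (no Platt/isotonic step); they are
  interpretable as corrected precisions, not calibrated frequencies.
- The RWR baseline ignores edge confidence scores.
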
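# Methods

## Scope and model

`netmod` implements a network-medicine workflow for localising a complex
disease on the protein–protein interactome and prioritising drug targets.
The workflow assumes (i) the interactome's high-confidence subset carries
meaningful community structure, (ii) disease genes cluster in a small
number of those communities (the disease-module hypothesis), and (iii)
drugs that act on the disease have targets topologically close to the
disease genes. Each stage below states its estimator, defaults, and the
choices that were genuinely open.

## Interactome

Input is a STRING-style weighted edge list (integer confidence 0–1000).
Edges with score below the threshold (default **700**, inclusive — the
conventional high-confidence cut) are discarded; duplicate lines in either
orientation are merged keeping the maximum score, and self-loops are
dropped with a logged count. Identifiers are uppercased and may be
remapped through an optional two-column alias table; beyond that, IDs are
opaque strings. Restriction to the largest connected component is
available behind a config flag but off by default, since the analysis is
well defined on a disconnected graph (unreachable targets are handled
explicitly downstream).

## Topological modules

Communities are found by Louvain modularity maximisation
(`networkx.community.louvain_communities`). The detector always partitions
once at the top level; any community above **max_size = 400** members is
re-partitioned on its induced subgraph, recursively, until every module is
within bounds or a community refuses to split (returned whole and flagged
`unsplittable`). Communities below **min_size = 5** are retained but
flagged `small`, and downstream stages exclude them from the analysed set;
they are never force-merged into modules the optimiser did not propose.

Modularity runs on the binary (score-filtered) graph by default; a
`weighted` switch uses confidence scores as weights. Rationale: after
filtering to a high-confidence subset the scores are compressed into
[700, 1000] and carry little additional signal. Determinism: subgraphs are
rebuilt with sorted node/edge insertion before each Louvain call, so one
seed yields one partition regardless of how the caller constructed the
graph.

The module graph places an edge between modules joined by `c >= 1`
interactome edges with weight `c / (a·b)` (`a`, `b` member counts) — the
realised fraction of possible cross-connections, equal to 1 exactly for a
complete bipartite join.

## Disease-module association

A module of `m` proteins containing `k` seed genes, against a background
of `S` mapped seed genes among `N` proteins in analysed modules, scores

    RR = (k/m) / (S/N),

with significance from the chi-square statistic of the 2×2 table
`[[k, m−k], [S−k, N−m−(S−k)]]` at 1 df, computed as Σ(O−E)²/E (no Yates
continuity correction by default; available by flag), Bonferroni-corrected
across the modules tested. The background is deliberately the
module-covered universe, not the full interactome: RR then measures
concentration relative to where seed genes can fall, and the screen's own
margins define the table. Module selection takes either a fixed RR
threshold or the RR of a named anchor module (the practice of using the
last multiple-testing-significant module as the cutoff). Per-disease
mapping repeats the computation with each disease's own mapped gene count
as `S`, keeping modules with `rr > 1` (configurable) and `k >= 1`.
Disease–disease similarity is Jaccard on their gene sets.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with universe `N` = the collection's annotated genes (not the
interactome; configurable), query `n` = module ∩ universe. The Bonferroni
family defaults to the terms with nonzero overlap for the query
(matching the behaviour family of the classic GO tools), switchable to
all terms in the collection; the factor used is logged. GO hierarchy
propagation is not performed — collections are flat GMT sets. Significance
threshold α = 0.05.

## Functional similarity

Per namespace, each module's profile vector holds `−log(p_corrected)` for
its significant terms and 0 elsewhere; corrected p-values are floored at
1e−300 before the log so underflowed values stay finite. Natural log is
used; the base cancels in cosine. Cosine similarity is taken over the
union of term spaces (all-zero vectors score 0 by convention; entries are
non-negative so values lie in [0, 1]). The combined score weights GO and
pathway evidence equally:

    combined = 0.5·(sim_BP + sim_CC + sim_MF)/3 + 0.5·sim_pathway.

Modules are clustered by Louvain on the similarity graph thresholded at
**min_combined = 0.05** (no published threshold exists for this graph;
0.05 keeps any non-trivial similarity while discarding numerically empty
edges, and is a config parameter). Modules with no retained edge are
reported as unclustered rather than as singletons.

## Drug-target proximity

Target–disease distance is the minimum hop count from the target to any
seed gene, computed with one multi-source BFS from the seed set (unit
edge costs; `1/score` costs available). Unmapped targets are dropped with
a logged count; targets that cannot reach any seed get a sentinel and are
excluded from statistics. The null draws **100** random protein sets of
the mapped-target size, uniform over nodes by default (degree-matched
sampling from log-degree bins is provided, since uniform sampling
over-represents low-degree proteins); observed distances are compared to
the pooled null distances with a two-sample pooled-variance t-test
(Welch by flag). The per-target-minima-versus-pooled-minima comparison is
one of two defensible readings of "randomized samples + Student's test";
the alternative (per-sample means) is not implemented.

Per module, the census counts direct targets (members), neighbour targets
(distance exactly 1 from the module's own seed genes, non-members),
distinct drugs with ≥ 1 direct target, and drugs per protein. Candidate
nomination within a disease module takes members of the module's
most-enriched pathway (minimum corrected p), removes genes already
targeted by drugs of the disease's own indication class, and — when an
expression table is supplied — genes not expressed in any required tissue
(default: cerebral cortex, hippocampus, the regions whose pathology
motivates the disease-relevance requirement).

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes, with ground truth recorded: a planted-partition (stochastic block
model) interactome — default five blocks of 100 nodes, within-block edge
probability 0.3, between 0.01 — whose confidence scores make within-block
edges high-confidence (≥ 700) with probability 0.9 and between-block
edges with probability 0.3, so the 700 filter thins noise but keeps
communities; diseases whose genes are drawn from designated home blocks
with a controlled leak fraction; annotation terms drawn inside a home
block (planted) or uniformly (decoys); drugs whose targets are placed
within a stated hop distance of the seed set (proximal, AED-like) or
uniformly; and an expression table with designated unexpressed genes.
All randomness flows through one integer seed and regeneration is
byte-identical.

What the generator does **not** model: realistic degree distributions
(edges are Bernoulli within/between blocks), GO DAG structure or term
overlap correlations, score–evidence correlation, or literature bias in
disease-gene curation. Passing tests therefore demonstrate that each
estimator recovers the structure it targets when that structure is
present and cleanly separated — not that real interactome snapshots would
yield any particular module count or candidate list.

## Test problem sizes and statistical margins

Recovery and calibration properties run at sizes chosen for clean
separation: community recovery on 500-node five-block graphs over 20
seeds (ARI ≥ 0.9 expected in ≥ 19); null calibration of the proximity
test over 50 replicates on a 300-node graph (rejections at 0.05 expected
≤ 14%); planted-proximal detection over 20 seeds. The disease-module
screen uses 10 planted modules among 50 (size 120) with seed densities
0.30 vs 0.06 (5×) and RR threshold 1.5 — roughly midway between the
expected planted RR of ≈ 2.8 and decoy RR of ≈ 0.56, where a normal
approximation puts the per-cohort failure probability near 1e−3, giving
the 19-of-20 criterion a comfortable margin. These conditions were fixed
by that power analysis, not tuned against test outcomes.

## Numerical notes and limitations

- Hypergeometric and chi-square tails come from scipy; the hypergeometric
  upper tail is verified exhaustively against closed-form enumeration for
  all universes N ≤ 12 at 1e−12.
- The binomial fold-enrichment validation needs an explicit gene-universe
  size (default 19,063, approximately the protein-coding gene count); fold
  scales linearly with it, so it is a required, documented parameter
  rather than a constant buried in code.
- Chi-square on tables with a zero margin returns (0, 1) rather than
  raising; RR is 0 when k = 0.
- Louvain is a heuristic: different seeds may yield different partitions
  of weakly modular graphs. Determinism is guaranteed per seed, global
  optimality is not.
- The t-test treats discrete hop counts as continuous; with ≥ 30 targets
  the normal approximation is adequate, and the calibration test verifies
  the realised size empirically.
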
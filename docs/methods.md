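# Methods

This note records the models, conventions and defaults behind `trnkit`, the
choices made where the methodology was genuinely open, and what the synthetic
benchmarks do and do not establish about real curated networks.

## Network model and input conventions

A regulatory network is a simple directed graph. Nodes are genes; a node is
annotated `TF`, `sigma` or `target` (target-only genes never regulate).
Edges carry a regulatory mode (activation / repression / dual / unknown) and
an evidence level (strong / weak / unknown). Duplicate rows for the same
ordered (regulator, target) pair — common in curated exports, where one
interaction appears under several promoters — collapse into one edge; an
activation and a repression record for the same pair reconcile to `dual`,
and the strongest evidence seen is kept. Autoregulatory self-loops are
biologically real and preserved. Declaring the same regulator id both TF
and sigma is a load error, not a warning: it always indicates a corrupted
table.

Identifiers are case-preserved for display but compared case-insensitively,
and sigma-factor spellings (`SigA`, `sigA`, `SIGA`) canonicalize to `sigA`,
because database exports mix conventions freely.

## Degree statistics and tail fits

Degree histograms include zero-degree nodes in the denominator; a self-loop
adds one to both the in- and the out-degree of its node. The CCDF conditions
on k ≥ 1 (log 0 is undefined), so CCDF(k_min) = 1 by construction.

Tail models are fitted to the CCDF by ordinary least squares: log10 CCDF
against log10 k for the power law, log10 CCDF against k for the
exponential; the model with higher R² wins, ties going to the power law
with a warning. Because a power law P(k) ∝ k^(−γ) has CCDF slope −(γ−1),
the fit reports both the raw slope and the implied P(k) exponent
(slope − 1), removing the classic off-by-one ambiguity between the two
conventions. The default fit range is all k ≥ 1 with a configurable k_min.
Least-squares CCDF regression is the historically standard estimator and is
kept as the primary method deliberately; maximum-likelihood (Clauset-style)
fitting is intentionally out of scope.

Clustering coefficients are computed on the undirected simple projection
(self-loops removed, reciprocal pairs merged); nodes with projected degree
< 2 contribute 0, and the mean is unweighted over all nodes. Directed
clustering variants exist but are not what the classic TRN literature used.

Hub coverage (the fraction of the network a regulator reaches in one step)
is reported with two denominators — all nodes, and all nodes except the hub
— since published percentages rarely state which was used.

## Association modules

On the regulator subnetwork the shortest-path length d_ij is computed by
BFS on the undirected projection, and the association s_ij = 1/d_ij² with
s_ii = 1 and s = 0 for unreachable pairs. The 1/d² transform amplifies
direct neighbourhoods (s = 1 exactly when the pair is adjacent) and
suppresses remote ones (d = 3 already gives s ≈ 0.11).

Two UPGMA dissimilarities are offered:

- `profile_correlation` (default): Pearson correlation distance between the
  *rows* of the association matrix. This mirrors the classic
  Cluster-3-on-a-data-matrix workflow — two regulators are similar when
  their association profiles to the whole network agree — and on planted
  block benchmarks it recovers the planted partition markedly better
  (ARI ≈ 0.97–1.0 versus ≈ 0.85 for the pairwise form at the same
  separation), because profile agreement integrates evidence over all n
  columns instead of relying on the single coarse-valued pairwise entry.
- `one_minus_association`: D = 1 − s directly, the straightforward pairwise
  reading; retained for comparability.

The dendrogram is cut either at an explicit module count or automatically.
The automatic rule finds the largest gap between consecutive merge heights;
since any network, structured or not, has *some* largest gap, the candidate
cut is accepted only if its Newman modularity on the regulator adjacency
(recoverable from the association matrix: s = 1 iff adjacent) reaches the
conventional 0.3 threshold, otherwise one module is reported. This gate is
what lets the method answer "no modular structure" on homogeneous networks
(50/50 correct on structureless calibration runs) while leaving planted
structure untouched (15/15 at the correct count).

Regulators unreachable from every other regulator (association 0 to
everything) are not clusterable in this geometry; each becomes its own
singleton module, numbered after the cut modules and reported separately,
matching the disconnected regulator groups curated TRNs display.

Girvan–Newman is the alternative method: iterative removal of the
maximum-edge-betweenness edge on the undirected projection, stopping at a
requested component count or at maximum modularity. All tie-breaks
(betweenness ties, merge ties) resolve on lexicographic node labels, so
both methods are bit-reproducible without any random state.

Partition comparison reports ARI, NMI, the pairwise module Jaccard matrix,
and a set relation (equal / subset / superset / overlap / disjoint) of each
module of one partition against the other — the vocabulary needed to state
that two methods agree "up to granularity".

## Motif census

FF and CFF are matched as induced subgraphs (mfinder convention): any edge
beyond the defining pattern — in particular any edge from the target back
to a regulator — disqualifies the triple, which makes the two classes
disjoint (a triple with the mutual regulator edge is CFF, never FF).
Self-loops are ignored for motif membership but stay in the graph. Edge
modes are ignored: the motif definitions are sign-blind. In a CFF the
mutual edge makes the two regulator roles symmetric; the instance is
emitted once with the lexicographically smaller regulator as master.

The null model is the standard switching randomization: pick two edges
u→v, x→y and rewire to u→y, x→v, rejecting swaps that would create a
self-loop or duplicate edge; every node's (in, out) degree pair is
preserved exactly, and the conservation law is asserted after every call.
Defaults are 1,000 randomizations and 100 swap attempts per edge; the
empirical p-value uses a +1 pseudocount, p = (1 + #{null ≥ observed}) /
(1 + n_random), so p can never be zero, and a motif type is significant
below 0.01. On fixtures up to a few hundred edges 10 swap attempts per
edge are far past mixing, so calibration runs and the acceptance script use
that value; the default stays at 100 as the conservative choice for larger
networks.

Embedding is decided on the regulator pair alone — a motif is embedded when
master and local share a module; the target is typically a structural gene
outside the regulator partition. Instances with an unassigned regulator
(e.g. an excluded hub) are listed separately rather than silently counted
in either bin. Role profiles count master and local appearances per
regulator; exact ties report "mixed".

## Synthetic generator

`SyntheticSpec` defaults describe a DBTBS-scale curated network: 70
regulators (a 0.2 sigma fraction, matching 16 of 70), ~1,550 structural
targets, nine regulator modules, out-degree exponent 2.1, a housekeeping
`sigA` hub wired to 46.5% of all nodes, 90% strong-evidence labels, and
block probabilities (0.15 within modules, 0.002 between) chosen so the
regulator-only subnetwork carries on the order of 80 edges, the size the
curated subnetwork has. Forty FFs and ten CFFs are planted on same-module
regulator pairs with fresh target genes; fresh targets guarantee the
planted triples survive induced matching, and planted edges are always
strong evidence so they survive filtering. Fan-out is drawn from a discrete
power law truncated to [1, n_targets] by inverse-CDF sampling. Generation
is a pure function of the spec: one `numpy` generator seeded from
`spec.seed` drives every draw, and the serialized output is byte-identical
across calls.

What the generator does *not* emulate: operon structure, the empirical
in-degree distribution of co-regulated promoters, correlated evidence
labels, or any evolutionary (duplication–divergence) mechanism. Passing
the recovery benchmarks therefore shows the pipeline detects the stated
kind of structure at the stated separation — not that any particular real
network has that structure.

One behaviour worth knowing: at paper scale the sigA hub dominates the
randomization ensemble, and the 40 planted FFs sit inside a large
hub-driven background, so *global* FF significance is not guaranteed on
default-spec networks (CFF, whose mutual edges are rare under the null,
is flagged reliably). The FF detection benchmark is therefore the
sparse-background configuration (40 regulators, 30 planted FFs, no hub),
where the planted excess is flagged at the smallest attainable p across
seeds. This mirrors the real caveat that motif z-scores on hub-heavy
networks are dominated by the hub's combinatorics.

## Numerical and degenerate-input choices

- Tail fits need ≥ 3 distinct positive-CCDF points, else
  `InsufficientDataError`; comparing fits computed on different point sets
  raises `FitRangeError`.
- An all-zero degree distribution has no CCDF (`DegenerateDistributionError`).
- Evidence filtering may legally empty a network (warning, not error);
  parsing an interaction-free file is an error.
- `switching_null` on < 2 edges, or when no valid swap exists, returns the
  input unchanged with a warning (some degree sequences have a unique
  realization).
- Requesting more modules than clusterable nodes raises `CutError`;
  comparing partitions with disjoint node sets raises
  `IncomparablePartitionsError`; partially overlapping node sets are
  intersected with a warning.
- Probabilities, exponents and block-probability ordering of a synthetic
  spec are validated up front (`SpecError`), including the requirement
  inter < intra that makes "planted structure" well-defined.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances: exhaustive checks on all 64 loop-free 3-node digraphs plus 100
random digraphs of up to 7 nodes against brute-force oracles; 200-seed
degree-conservation sweeps on a 50-regulator fixture; 25–50-seed recovery
sweeps on 40-regulator planted-partition networks; tail-exponent recovery
from 2,000-draw samples averaged over 5 seeds (single-sample least-squares
CCDF slopes scatter by ~±0.15, which is an estimator property, not a bug);
and one full-pipeline run at the default (paper-scale) spec with 1,000
null randomizations. These sizes were chosen so every result is recomputed
from scratch in seconds while keeping the Monte-Carlo noise below the
margins asserted.
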
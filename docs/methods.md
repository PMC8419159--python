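# Methods

This note documents the models, conventions and numerical choices behind
`hubnet`, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one defensible convention exists.

## Network model

All stages operate on a simple, undirected, loop-free graph over gene-symbol
labels. Edge weights are read from input files and retained for provenance,
but every computation is purely topological: PPI edge confidences are too
heterogeneous across sources to enter centrality or density formulas
meaningfully, and the ranking stage is invariant to any positive rescaling
anyway. Parallel edges collapse keeping the maximum weight; self-loops are
dropped with a warning (the density and clustering formulas below assume
loop-free graphs). Gene symbols are case-sensitive by default — curated
lists mix dialects (IL-6 vs IL6, mTOR vs MTOR), and silent case-folding
hides fixture transcription errors — with an opt-in `normalize_case` flag.

## Centrality conventions

Seven indices feed the ranking; the clustering coefficient is computed and
reported but is descriptive only.

- **Degree** deg(v) = |N(v)|.
- **Betweenness** B(v) = Σ_{s<t, s≠v≠t} σ_st(v)/σ_st, unnormalized,
  unordered pairs counted once, exact shortest-path counting (Brandes
  accumulation via networkx) — never sampled.
- **Closeness** 1/Σ_w d(v,w) over nodes reachable from v. On disconnected
  graphs the sum is component-restricted; an isolated node scores 0.
  (The alternative — treating unreachable nodes as distance ∞ and zeroing
  the whole graph — makes every index trivial on any disconnected input.)
- **Eccentricity** 1/max_w d(v,w) over reachable w; isolated node 0.
- **Centroid value** min_{w≠v} [γ_v(w) − γ_w(v)] where γ_v(w) counts nodes
  *strictly* closer to v than to w; equidistant nodes count for neither
  side, v itself counts for v and w for w, and opponents range over v's
  component (singleton components score 0). This gives the star K1,3 the
  values +2 (center) / −2 (leaves) and the 3-path +1 / −1.
- **Bridging** B(v) · BC(v) with BC(v) = deg(v)⁻¹ / Σ_{i∈N(v)} deg(i)⁻¹
  (BC = 0 for isolated nodes): high for modest-degree nodes whose
  neighbours are highly connected — the signature of inter-cluster bridges.
- **Eigenvector** principal eigenvector of the adjacency matrix of the
  largest connected component (ties broken by size, then smallest node
  label), non-negative and L2-normalized over that component, 0 elsewhere.
  Computed by power iteration on A + I from a uniform start vector: the
  unit shift makes the iteration matrix primitive, so the iteration also
  converges on bipartite components, where plain power iteration on A
  oscillates between the ±λ eigenspaces. Defaults: tol 1e−10 on the
  successive-iterate residual, max_iter 10000, no randomness. Failure to
  converge raises with the residual rather than returning silently.
- **Clustering coefficient** C_i = 2n/(k_i(k_i−1)) with n the number of
  edges among the k_i neighbours of i; defined as 0 when k_i < 2.

Every index is verified against an independent brute-force oracle
(hand-rolled BFS, layer-DP path counting, dense eigendecomposition, triple
loops over the definitions) on 50 seeded random graphs with n ≤ 30 to
1e−8, plus closed forms on cliques, paths, stars, cycles and a barbell.

## MCODE

Vertex weight = k_max × density of the highest k-core of the *closed*
neighbourhood N[v] (self-inclusive, per the original algorithm); nodes with
degree < `degree_cutoff` get weight 0. Prediction seeds from the
highest-weight unassigned node and admits neighbours breadth-first while
their weight ≥ (1−VWP)·w(seed), to at most `max_depth` hops; a node joins
at most one complex during prediction (fluff is the only sharing
mechanism), and single-node results are discarded. Post-processing drops
candidates with no 2-core, then optionally haircuts (iterative removal of
members with exactly one intra-complex edge) and fluffs (adds outside
neighbours whose closed-neighbourhood density exceeds the fluff threshold;
fluffed nodes may be shared). Density is always the loop-free 2E/(n(n−1));
score = density × size; ranking is by descending score with ties broken by
larger size then lexicographically smallest member set, which together with
sorted seed/neighbour iteration makes the whole stage independent of node
insertion order.

Defaults are the published ones — VWP 0.2, degree cutoff 2, haircut on,
fluff off (threshold 0.5), max depth 100.

## Rank aggregation

Per-centrality ranks are descending-value with average ties. The composite
is the unweighted arithmetic mean of the seven ranks — the minimal choice
when no index is to be preferred; the sum is rank-equivalent. Final ranks
sort by ascending composite with lexicographic symbol tie-breaking, so they
always form a permutation of 1..N regardless of platform. The hub cutoff
defaults to rank 25, and the criteria-profile bound `top_k` defaults to the
cutoff; both are flags. Higher value = better for all seven indices —
including centroid, which may be negative but remains higher-is-better.

## Enrichment

The over-representation p-value is the exact hypergeometric upper tail
P(X ≥ x) for drawing the query from the universe; the EASE variant
jackknifes one overlapping gene, P(X ≥ x−1), and is therefore ≥ the plain
tail everywhere (identically 1 when x ≤ 1). The universe defaults to the
gene background actually analyzed — the network's node set — not the
genome. Sets with fewer than 2 effective members or covering more than
half the universe are skipped with a log line. Significance is flagged on
raw p at α = .05, with Benjamini–Hochberg q-values always reported
alongside so a stricter FDR reading needs no recomputation. Note that the
BH step-up adjustment is not an idempotent operator (re-adjusting q-values
can only raise them); the suite asserts order-invariance, q ≥ p and
order preservation instead.

## Comparative Ct

ΔCt pairs the target with the reference gene measured in the same sample
*and replicate* (configurable to the sample's mean reference Ct): pairing
preserves the replicate-level correlation of pipetting and efficiency
effects. ΔΔCt contrasts pooled group means; RQ = 2^−ΔΔCt; RQ < 1 is
additionally rendered as a decrease fold 1/RQ, the convention for reporting
down-regulation. Hypothesis testing runs on ΔCt — the log2 scale, where
technical noise is approximately additive Gaussian — with an equal-variance
two-sided Student's t test (Welch behind a flag); when both groups are
exactly constant the p-value is 1 for equal means and 0 otherwise.
Dispersion is summarized as the SEM of per-sample RQs (each treated
sample's mean ΔCt against the pooled control mean), the display convention
for error bars over independent experiments. Genes with no amplification
rows are flagged undetectable and never imputed. No cross-gene multiplicity
correction is applied by default (a BH option exists), matching how small
qPCR panels are conventionally reported.

## Synthetic generators

`gen_planted_module_graph` draws an Erdős–Rényi background G(n, p) and
resamples each planted module's internal edges at its stated density;
a Barabási–Albert background is available because real PPI networks are
heavy-tailed, but ER is the default for its analytical transparency. The
default study condition used throughout the tests and the acceptance script
is G(200, 0.03) with one planted 8-clique: sparse enough that the densest
background structure scores well below the planted complex, matching the
regime where complex detection is meaningful.

`gen_ct_table` mirrors the qPCR design it emulates: conditions
{control, treated} × timepoints {6, 24} h × three independent experiments ×
duplicate technical replicates, a stable reference gene (GAPDH), one
baseline Ct per gene drawn uniformly from 18–30 cycles, and i.i.d. Gaussian
noise per measurement with σ defaulting to 0.2 cycles (a typical technical
SD for SYBR assays). The treated shift is −log2(fold) cycles, so the
analysis should recover RQ = fold.

What the generators deliberately do **not** emulate: evidence-channel
heterogeneity of real interaction databases (co-expression vs physical
edges), degree-correlated annotation bias in gene sets,
amplification-efficiency differences between primer pairs, inter-plate
batch effects, and non-Gaussian Ct outliers from failed wells. Passing
tests therefore demonstrate correctness of the algorithms under their
stated statistical assumptions, not robustness to every artifact of bench
data.

All generators are pure functions of their arguments including the seed
(NumPy `default_rng`); truth objects record the seed, and identical calls
produce byte-identical serialized outputs.

## Problem sizes

The verification suite uses n ≤ 30 graphs against brute-force oracles (50
seeds), G(200, 0.03) × 20 replicates for planted-complex recovery, an
exhaustive hypergeometric grid up to N = 25, 200 null replicates for
enrichment calibration (the null design — universe 500, query 80, set
sizes 40–160 — was chosen by computing the exact attained level of the
discrete test, ≈0.037 at nominal .05, before any simulation), and 50
replicates per cell of the fold/noise recovery grid. These sizes give
stable statistics while keeping the full suite in the tens of seconds.

## Known limitations

- Centroid and bridging follow the CentiScaPe and Hwang et al. definitions
  respectively; other tools ship subtly different variants, so absolute
  values (not ranks) may differ across software.
- Eigenvector centrality covers only the largest component; analyses where
  minor components matter should be run per component.
- MCODE's greedy prediction is order-deterministic here but, like the
  original, not globally optimal; overlapping complexes arise only via
  fluff.
- The enrichment test assumes exchangeable genes within the universe; it
  inherits none of DAVID's curated category structure or background
  corrections.
- The ΔΔCt model assumes equal amplification efficiency between target and
  reference (no Pfaffl correction) and a reference gene that is truly
  stable across conditions.
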
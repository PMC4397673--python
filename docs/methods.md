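# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make runs reproducible.

## Symbol handling

Gene symbols from ChIP catalogs (typically upper-case), PPI exports
(mixed-case) and expression matrices are joined after normalising every
symbol to a canonical capitalised form (`SOX2`/`sox2` → `Sox2`). Multi-source
mouse data cannot be joined reliably any other way without vendor annotation
files, which are out of scope. The join is lossy only if a data source
genuinely distinguishes symbols by case, which mouse/human symbol
nomenclature does not.

## Differential expression (`diffexpr`)

DE genes are called purely by fold change: with log2 expression, the
statistic is `log2FC = mean_B − mean_A` and a gene is DE when
`|log2FC| ≥ log2(threshold)` (default threshold 3, deliberately restrictive
to suppress background noise; TFs are separately tested at 2-fold for the
DE-TF rule). Fold change is the ratio of linear-scale group means —
equivalently the difference of log2 means on log input; a config switch
(`expression_scale: linear`) log-transforms linear input first. Duplicate
probe rows collapse to the row with maximal `|log2FC|` (ties: first in file
order).

Welch's two-sided t statistic supplies per-gene p-values. These do **not**
gate the DE call (no multiple-testing control is applied to DE calling,
which is threshold-based); they exist because the active-module stage
aggregates per-gene p-values. With fewer than two samples per group, or
degenerate variance, p is set to 1.

## Enrichment (`enrichment`)

*TF enrichment* is the one-sided upper-tail hypergeometric
`P(X ≥ k)` with population = measured universe after probe collapse (not the
genome — a DE list from an array conditions on what the array measures),
successes = catalog targets ∩ universe, draws = DE genes. A TF is a DE-TF
iff `p ≤ α` (default 0.05) **and** its own expression changes ≥ 2-fold; TFs
absent from the matrix can never be DE-TFs.

*Pathway enrichment* uses the doubled two-sided tail
`min(1, 2·min(P(X ≤ k), P(X ≥ k)))` with enrichment/depletion decided
against the hypergeometric mean `nK/N`, and Holm (Bonferroni step-down)
adjustment over all tested sets. The tail conventions mirror the tools this
emulates: over-representation catalogs report one-sided enrichment; the
"enrichment versus depletion" pathway statistic is two-sided.

## Network assembly (`network_build`)

Nodes are the DE-TFs plus every DE gene regulated by one
(`targets(f) ∩ DE`); regulatory edges run DE-TF → DE target; PPI edges are
retained only when **both** interactors are network nodes, i.e.
differentially expressed — the only reading of "PPI filtered by the
expression of the interacting counterparts" computable from the stated
inputs (a one-endpoint variant would be a one-line change). TF self-loops
are retained and flagged. The separate TF PPI network takes the DE-TF
proteins plus their direct PPI partners, with all PPI edges among that node
set (partner–partner edges included, which is how first-neighbour BioGRID
networks grow beyond the seed proteins).

## Motif census (`motif_census`)

Counting is *induced*: every connected 3-node subgraph (connectivity on the
union of the regulatory and PPI layers) contributes exactly one instance.
A triad is encoded as a 12-bit state — 3 color bits, 6 directed-edge bits,
3 undirected bits — and classified by the minimum encoding over all 3!
relabelings; the 4096-entry canonicalisation table is precomputed, making
classification O(1). Regulatory self-loops do not participate in triads.

The null is degree-preserving edge switching applied independently per
layer: directed swaps `(a→b, c→d) → (a→d, c→b)` preserve in/out degrees;
undirected double-edge swaps preserve degree; proposals creating self-loops
or duplicates are rejected; attempted swaps = 10 × layer size; node colors
never move. Per-layer switching does not preserve cross-layer pair overlap
(a pair with both a reg and a ppi edge may decouple) — the standard
colored-edge convention, and exactly the property that makes "one TF
regulates two genes whose proteins interact" detectable as a motif. Null
mean/sd use the sample estimator (ddof = 1); `z = (N_real − μ)/σ`, with NaN
when σ = 0 and the real count equals μ, and ±∞ sentinels otherwise;
`p_empirical` is the fraction of random networks reaching the real count
(resolution 1/n_random). A class is flagged a motif at z ≥ 2 and p ≤ 0.05.
Classes never seen in the real network are not reported.

Calibration caveat: for classes whose expected count is ≪ 1 the z statistic
is intrinsically heavy-tailed (a count of 1 against a mostly-zero null gives
|z| ≈ 4 for any correct implementation). The null-soundness benchmark
therefore uses mixed ER graphs dense enough (n = 40, p = 0.1 per layer) that
the typical class recurs; on very sparse graphs the flagged fraction should
be read with that caveat.

## Centrality (`centrality`)

All six parameters are computed on the undirected union graph with unit
weights, per connected component (direction is ignored for distances, as the
classic plugin did; mixed reg/PPI layers share one metric). Reciprocal forms
`eccentricity = 1/max_t d(v,t)` and `closeness = 1/Σ_t d(v,t)` make
"higher = more central" uniform across parameters. Betweenness and stress
exclude endpoints and count each unordered pair once. Centroid is
`min_w (γ_v(w) − γ_w(v))` with `γ_v(w) = #{u : d(u,v) < d(u,w)}` (v itself
always qualifies). Nodes in singleton components report zeros. Betweenness
comes from networkx (Brandes); stress and centroid from an all-pairs BFS
distance/path-count matrix, vectorised per node.

The hub consensus rule — sort by the count of parameters strictly above
their component mean, then degree, then symbol — is this package's explicit
instantiation of "ranked based on the results of these parameters", which no
tool of that era pinned down; it is deterministic and documented rather than
implicit.

## Dense complexes (`mcode`)

`weight(v) = k_max · density(k_max-core of N[v])` over the closed
neighbourhood; complexes grow breadth-first from the unvisited
highest-weight seed, admitting neighbours with `weight ≥ (1 − vwp)·
weight(seed)` (vwp default 0.2, the original default), each vertex in at
most one complex. Haircut iteratively removes members with fewer than two
in-module neighbours but is skipped for 2-node modules — otherwise a real
two-protein complex (score exactly 2) could never be reported; the score
threshold (default: strictly > 2) has an inclusive switch for exactly that
borderline. Score = density × size. Ties everywhere break lexicographically,
so output is deterministic. Fluff/overlapping membership is not implemented.

## Active modules (`active_modules`)

Node scores are `z_i = Φ⁻¹(1 − p_i)` with p clipped into
`[1e−12, 1 − 1e−12]` (finite z under underflow; p = 1 from degenerate Welch
tests is accepted and clipped). A set A scores `Z_A = Σ z_i/√|A|`.

Raw Z is not comparable across sizes: even on null data the *best found*
subnetwork of size k has an inflated Z that grows with k. The corrected
score is therefore `(Z_A − μ_k)/σ_k` where μ_k, σ_k are the mean and sd of
the best Z at size k found by running the *same* greedy search on
score-permuted data (default 200 permutations, 10 seeds — the max-statistic
calibration of the classic tool). Calibrating against uniform random
k-subsets instead (exposed as `background_calibration`, with closed-form
moments `μ_k = √k·z̄`, `σ_k = S·√((N−k)/N)` in `subset_moments`) measurably
under-penalises growth: any neighbour with `z ≳ Z_A/(2√k)` (~1.2 in the
benchmark regime) still improves the subset-corrected score, so the
maximizer absorbs moderate-z background and planted-module recovery
collapses (Jaccard ≈ 0.5–0.79). The max-search calibration prices in the
search's own opportunism and stops growth at the module boundary.

Search: from each of the top-z seed nodes, grow by repeatedly adding the
best-z frontier node (ties by symbol) to the size cap, score the trajectory
at every size, and take the argmax prefix as that seed's candidate;
candidates are returned best-first with pairwise Jaccard ≤ 0.5 (the filter
can be disabled — overlapping modules are biologically real). Simulated
annealing is deliberately not reproduced: the greedy search is deterministic
given the seed and sufficient for planted-structure recovery; an annealing
schedule would add nondeterminism without a recorded reference schedule.

## TF ranking and consensus (`tf_ranking`)

The TF × pathway matrix is `cell(f, P) = |targets(f) ∩ DE ∩ P| / |DE ∩ P|`;
columns with no DE genes are omitted (never 0/0), and rows are ordered by
row mean (the natural reading of published tables of this kind, which are
visibly near-sorted by magnitude). Regulators of a designated gene set rank
by `|targets(f) ∩ DE ∩ set|`, ties alphabetical.

Within a study, the consensus is TFs present in ≥ m of the named analysis
lists (hubs, complexes, active modules; m = 2 by default); master regulators
order by (number of supporting analyses, symbol). Across ≥ 2 studies, TFs
present in every study are tabulated with per-study direction; only
direction-concordant TFs (sign of log2FC, magnitude ignored) become
cross-study master regulators, ordered by total supporting analyses. A
single-study run reports its within-study consensus as its master-regulator
list.

## Synthetic data (`synthetic_data`)

`simulate_study` emulates a normalized two-condition microarray comparison:
log2 baseline N(7, 1) per gene, per-sample noise N(0, 0.25), a planted DE
fraction (default 0.1) with shifts ±|N(lfc_mean, lfc_sd)| split half
up/half down (defaults lfc_mean = 3 ≈ log2 8, sd 0.5 — a strong-signal
regime in which the 3-fold rule should recover essentially all planted
genes; calibration examples pass weaker means explicitly). The first
`n_tfs` symbols are TF-coding genes. Planted *enriched* TFs (default 5) are
forced into the up-regulated DE set (so the 2-fold TF rule can fire), draw
their regulon from the DE pool with probability
`min(0.9, de_fraction × enrichment_boost)` (boost 1 ⇒ background
behaviour), and anchor the planted PPI clique and the planted active module
(DE genes wired as their targets, hence connected through them). Regulon
sizes are jittered Uniform(0.5, 1.5) × `targets_per_tf` because real ChIP
catalogs have widely dispersed regulon sizes — this also smooths the
discrete hypergeometric p-value distribution, which matters for the null
calibration checks. PPI background is ER among TF proteins at density 0.02.
Everything is reproducible from one integer seed.

Not emulated: probe-level structure, batch effects, correlated noise,
platform differences, scale-free global topology, and annotation ambiguity.
Passing recovery tests therefore show algorithmic correctness under the
stated statistical model, not robustness to real microarray artefacts.

Benchmark generators: `planted_motif_network` (40 node-disjoint copies of
"TF regulates two genes whose proteins interact" over random reg/PPI
noise), `planted_clique_ppi` (disjoint K5s + sparse ER background + bridge
edges), and `planted_p_network` (spanning tree + 0.3·n shortcuts, average
degree ≈ 2.6 — the sparse regime of biological interaction networks, and
the regime in which an aggregate-z module boundary is identifiable at all;
module p ~ U(0, 0.01) vs U(0, 1) background).

## Problem sizes and numerical conventions

Tests and the acceptance script run studies at n_genes = 1000–2000,
n_tfs = 100–200, 3 samples/group, motif nulls of 100–1000 random networks
and 200 score permutations for module calibration — sizes chosen so the
full suite exercises every stage end-to-end on desk hardware while leaving
every statistical conclusion (calibration bands, recovery rates) stable
across seeds. Reported quantities that depend on the original accessions
(absolute DE counts, node/edge totals, the published motif count) are
data-dependent and are not reproduction targets; the suite instead checks
exact oracles (rational-arithmetic hypergeometric tails, brute-force triad
enumeration, BFS path counting, min-degree peeling) and planted recovery.

Floating-point/degeneracy conventions: hypergeometric tails delegate to
scipy (verified to < 1e−12 against exact rational sums for N ≤ 60); Holm
via statsmodels; motif z sentinels as above; sd floors of 1e−9 guard
corrected-score divisions, with exact-zero differences reported as 0; all
orderings have total, documented tie-breaks so identical inputs give
byte-identical outputs.

## Known limitations

- The PPI "significance" filter is expression-based only; no evidence-code
  or interaction-score weighting.
- Per-layer randomization decouples reg/ppi multi-edges (documented above);
  motif z-scores for classes with expected count ≪ 1 are heavy-tailed.
- Greedy module search finds one good local optimum per seed; it does not
  enumerate alternative optima as annealing variants can.
- The hub-consensus and master-regulator orderings are package conventions;
  alternative aggregations (rank products, Borda) would be drop-in
  replacements.
- The case-normalised symbol join cannot resolve genuine cross-platform
  annotation conflicts.
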
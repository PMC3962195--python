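# Methods

This note documents the statistical and algorithmic choices behind
`netgba`, the parameters that matter, and what the synthetic benchmark
does and does not demonstrate.

## Differential expression

Quantile normalization maps every sample column onto the across-sample
mean of order statistics; tied values receive the average of the target
values they span (average-rank convention), so within-column order is
preserved up to ties.

The moderated t follows the standard empirical-Bayes treatment of
gene-wise variances. For a two-group contrast with n₁ + n₂ samples, each
gene's pooled residual variance s² has d = n₁ + n₂ − 2 degrees of
freedom. The prior (d₀, s₀²) is estimated by method of moments on
z = log s²: with e = z − ψ(d/2) + log(d/2), the excess of Var(e) over
ψ′(d/2) determines d₀ through the inverse trigamma (Newton iteration),
and s₀² follows from the mean of e. When the observed spread of
log-variances does not exceed the sampling noise, d₀ = ∞ and every gene
is shrunk fully to s₀². The posterior variance is
(d₀ s₀² + d s²)/(d₀ + d) and p-values use d₀ + d degrees of freedom. The
implementation is verified against the Bioconductor reference
implementation to 1 × 10⁻⁶ on t for a shared fixture, and recovers
generating hyperparameters (d₀ = 4, s₀² = 0.05) within 25% at 5,000
genes.

p-values are deliberately unadjusted for seed selection: the workflow
compensates by intersecting significance across contrasts and tightening
the cutoff (0.05 → 0.01) rather than by per-contrast FDR control, which
on small post-mortem cohorts leaves too few genes to analyze. BH/
Bonferroni-adjusted columns are available post hoc.

The contrast model is a two-group mean difference only (no covariates,
no pairing). Probe-level inputs can be collapsed to symbols by the
best-p-per-symbol rule before intersection, so that seed counts are gene
counts.

## Seed selection

Each dataset contributes one significance list per tissue plus a pooled
"diagnosis" contrast; the dataset core is the intersection of all its
lists (strict p < α), cores are unioned across datasets, and the final
tightening keeps genes with p < 0.01 in every contrast of at least one
dataset. Venn region counts are reported per dataset for 2–4 sets.

## Subnetwork construction

All distances and degrees use the undirected simple view of the typed
multigraph: parallel edges of different interaction type are preserved
for reporting but a node's degree is its distinct-neighbor count, and
direction/sign are carried as edge attributes only. Self-loops are
dropped on input.

The shortest-path network includes **all** geodesics per seed pair (not
one arbitrary representative), which makes the construction
deterministic and order-independent; `max_len` (default 2, i.e. at most
one intermediate connector) bounds the geodesic length considered. The
default reflects the target regime of connector-to-seed ratios around
1.5–2:1; longer paths pull in disproportionately many intermediaries.

The compact variant filters seeds by distinct-neighbor count in the
*full* interactome (default 25, calibrated to curated interactomes with
10⁵–10⁶ edges; for the synthetic benchmark, whose mean degree is ~7, the
density-equivalent value of 5 is used). Components are then reconnected
greedily: at each step the single interactome node adjacent to the most
components is added with all its edges, ties broken by higher global
degree then alphabetically. This is a declared stand-in for the
unspecified "few generic genes" step of interactive tools; it makes no
Steiner-tree optimality claim, but on small instances it matches
exhaustive search over few additions, and unmergeable components are
reported rather than force-joined.

## Centralities

Closeness is component-local, (n_c − 1)/Σ d(v, u), which is well defined
on the disconnected direct-interaction networks this workflow produces
(harmonic centrality was rejected to keep the reported quantity the
familiar closeness). Betweenness excludes endpoints, splits credit
fractionally over equal-length geodesics, and is normalized by
(n − 1)(n − 2)/2 within each component. Both are defined operationally by
equivalence to exhaustive path enumeration on graphs of ≤ 8 nodes
(verified over 200 random graphs at |Δ| < 10⁻⁹); the implementation
delegates to networkx. Rank order, not raw value, is the comparable
quantity across normalization conventions.

Top-k reports break ties alphabetically and include (flagged) every node
tied with the k-th score; hub status is strict degree > threshold
(default 15).

## Guilt by association

A node's GBA score counts its distinct first neighbors belonging to the
known-disease list, computed on the compact shortest-path network (the
delivery network of the workflow), not the full interactome. The
four-way classification (known/of-interest × seed/connector) implements
the computable core of candidate status: non-known nodes qualify as "of
interest" with ≥ 1 known neighbor or a top-10 rank on any centrality
measure. The manual literature-review component of candidate curation is
out of computational scope by design.

## Enrichment

Exact hypergeometric upper tail P[X ≥ k] (scipy), fold enrichment
(k/n)/(K/N), BH step-up q-values (statsmodels), both verified against
direct combinatorial summation, 10⁵-draw Monte-Carlo sampling, and
hand-computed step-up examples. Sets with K < 3 or K > 500 are excluded
by default. The query is restricted to the collection's background; the
background defaults to the union of set members unless supplied.

The mechanism gene list is the **union** of member genes across selected
enriched pathways — pooling the pathway memberships is what reproduces
the reported 46-gene mechanism list, whereas a literal intersection of
the sixteen sets is nearly empty. Curation of which enriched terms to
keep (e.g. dropping cancer/infection pathways) is exposed as a term
blocklist file, not encoded as judgment.

## miRNA layer

The bipartite map uses only `mirna_regulation` edges incident to seed
genes. The miRNA side of an edge is identified by node kind (naming
pattern `miR-`/`hsa-miR-`/`let-7`, or an explicit declaration); an edge
of this type between two gene-kind nodes is a validation error rather
than a silent guess, keeping the bipartite invariants testable. No
target prediction is performed — edges come from the input interactome,
and an optional per-edge evidence column passes through unmodified.

## Synthetic benchmark

The generator emulates the study conditions: 2,000 genes, a
preferential-attachment interactome (m = 3) for a heavy-tailed degree
distribution, a planted 50-gene module made connected by a random
spanning tree plus 50 extra intra-module edges, 15 known genes inside
and 10 outside the module, each non-known module gene wired to 2 known
module genes (the GBA signal), three tissues with 8 cases vs 8 controls,
a log2 effect of 1.5 on module genes in **all** tissues (so the
multi-contrast intersection can capture the module) over noise SD 0.5
around per-gene Normal(8, 1) baselines, 20 miRNAs of out-degree 8 with
70% module bias, and 30 gene sets of 40 genes of which one draws 60% of
its members from the module. All stages derive independent child
generators from the single `rng_seed`, so bundles are byte-identical
across re-runs.

What passing recovery tests shows: under a clean additive effect with
homogeneous noise and a module wired as described, the pipeline
recovers ≥ 80% of module genes as seeds, ranks module genes above
background by GBA (Mann-Whitney p < 0.01), and assigns the planted set
the minimum q ≤ 0.05. What it does not show: robustness to probe-level
artifacts, post-mortem degradation, batch effects, variance
heterogeneity between groups, or annotation incompleteness — none of
which the generator simulates.

## Numerical and degenerate-input choices

- Strict inequalities where thresholds are stated as such: seed
  significance p < α, hub degree > threshold.
- Zero-variance genes with d₀ = 0 yield undefined t, reported as NA.
- Isolated nodes have closeness 0 and serialize as bare-symbol rows so
  edge-list round-trips preserve the node set exactly.
- Unknown interaction-type strings are rejected by default (or mapped to
  `regulation` on request); malformed rows fail with their line number.
- All orderings (rankings, reports, edge lists) are deterministic with
  alphabetical tie-breaks.

## Problem sizes

Tests run the oracle equivalences at 200 random graphs of ≤ 8 nodes,
shortest-path fixtures of 300 nodes/30 seeds, 5,000 simulated genes for
hyperparameter recovery, and one full synthetic pipeline run at the
default conditions; the acceptance script repeats the worked examples
and one full synthetic run per seed. These sizes keep a complete run in
the tens of seconds while exercising every stage at non-trivial scale.

## Known limitations

- No edge-weighted or directed shortest paths; direction is reported,
  never used for traversal.
- The greedy reconnection rule is one reasonable instantiation of an
  under-specified step; alternatives (Steiner approximations) would
  change the generic-node set.
- Enrichment results depend strongly on the background definition;
  fold-enrichment values are not comparable across annotation databases.
- Probe-to-gene collapse by best p is anti-conservative for genes with
  many probes; it is applied before intersection, where the effect is
  mitigated by the multi-contrast requirement.
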
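# Methods

## Overview

`mirspan` ranks microRNA families by their global regulatory influence over a
seed-gene interaction network. The pipeline has four computational stages —
seed-network construction, spectral modularity clustering, hypergeometric
target enrichment, and spanning-score ranking — plus a gene-set enrichment of
the network genes and the assay statistics used downstream (percent input,
ΔΔCt, exact Mann–Whitney, Pearson). This note records the model, the
parameters that matter, the design choices made where the design was open,
and the limits of what the synthetic tests demonstrate.

## Seed network

Seeds are gene symbols (uppercased, no alias resolution — unmapped symbols
are reported, never guessed) intersected with the interactome's node set.
The network is the interactome-induced subgraph on mapped seeds plus all
their first-degree interactors. Two open choices, and how they were fixed:

- **Interactor–interactor edges are kept** (induced subgraph). Module
  structure among interactors is only meaningful if their mutual edges are
  present; `seed_incident_only=True` gives the stripped variant for
  sensitivity analysis.
- **No minimum seed-connectivity filter** on interactors by default
  (`min_seed_links=1`); isolated mapped seeds are retained because they
  remain part of the tested gene set.

The interactome is undirected and unweighted: edge direction and any columns
beyond the first two of the edge list are ignored, since clustering and
enrichment use topology only. Note that an edge-list export cannot represent
isolated nodes, so a written-then-reloaded interactome consists of the
non-isolated genes; the pipeline's universe is whatever the loaded file
contains.

## Modularity clustering

Partition quality is Newman–Girvan modularity
`Q = Σ_c [e_c/m − (d_c/2m)²]`. Modules are found by recursive
leading-eigenvector bipartition of the generalized modularity matrix
restricted to the current module, with:

- **Refinement**: deterministic Kernighan–Lin single-vertex moves after each
  eigenvector split (every vertex moved once per pass in best-gain order,
  best prefix kept, passes repeated while Q improves).
- **Stopping**: a module is indivisible when the leading eigenvalue is
  ≤ 1e-9, when the refined split does not increase Q by more than 1e-12, or
  when a part would fall below `min_module_size` (default 3 — micro-modules
  are not useful enrichment strata; configurable).
- **Determinism**: nodes are processed in sorted symbol order; `numpy.eigh`
  is deterministic; the eigenvector sign is fixed by making its
  largest-magnitude entry positive; exact zero entries join the group of the
  lexicographically smallest symbol. Connected components are partitioned
  independently (the generalized matrix uses whole-graph degrees and m).
  Final labels are assigned in decreasing module size, ties broken by the
  smallest member symbol, so any input ordering yields the identical
  clustering.

An edgeless network (possible when a single isolated seed maps) is assigned
singleton modules with Q recorded as 0 by convention; `modularity()` itself
refuses edgeless input, where Q is undefined.

The test suite checks the partition against exhaustive search over all set
partitions on graphs of ≤ 8 nodes (≥ 95% of the optimum — the spectral
heuristic is not guaranteed optimal) and against planted-partition recovery
(adjusted Rand index ≥ 0.9 at 8 blocks × 15 nodes, p_within 0.6,
p_between 0.02).

## Target enrichment and the spanning score

All tests are upper-tail hypergeometric: drawing n genes from a universe of
N containing K family targets, the p-value is P(X ≥ k) (via `scipy`'s
survival function; P(X ≥ 0) = 1 exactly). The universe defaults to the full
interactome node set; a `universe="targets"` option restricts it to
interactome genes that appear in the target table's gene space. For each
family the network-wide test uses n = network size, and each module test
uses n = module size, so per-module overlaps always sum to the network
overlap.

The spanning score is

    S = B + (1 − p_net),    B = #{modules with per-module p < α},  α = 0.05.

Rationale: the score should reward a family whose targets modulate a
*diverse range* of processes, so module breadth is the dominant (integer)
term and whole-network enrichment the fractional tie-breaker, giving
S ∈ [0, n_modules + 1). Per-module p-values are deliberately **not**
multiplicity-adjusted inside B — B is a descriptive breadth count, not an
inferential family-wise claim; FDR control is applied only to the hallmark
table. The presence-based breadth (`clusters_with_targets`, the number of
modules containing ≥ 1 target) is reported alongside, and α is configurable.
Ranking is by descending S with deterministic tie-breaks (smaller p_net,
then larger network overlap k, then family id); families with zero
interactome targets are retained with p = 1 everywhere and S = 0 so the
ranked list always has one row per input family.

Gene-set (hallmark-style) enrichment applies the same hypergeometric test to
the network gene list over a GMT collection, restricted to sets intersecting
the universe, with Benjamini–Hochberg adjustment (via `statsmodels`) across
the tested sets.

## Assay statistics

- **Percent input**: `adjusted_input_ct = ct_input − log2(1/f)` for input
  fraction f (default 0.1, i.e. a 10 µL input aliquot of 100 µL chromatin),
  then `percent = 100 · 2^(adjusted_input_ct − ct_ip)`. Amplification
  efficiency is fixed at 2.0 per cycle (comparative TaqMan assays without
  efficiency calibration); the computation is invariant to a common Ct shift.
- **ΔΔCt**: per-sample relative expression `2^−(ct_target − ct_reference)`;
  group fold change `2^−(ΔCt̄_A − ΔCt̄_B)`.
- **Exact Mann–Whitney**: U = #{x > y} + ½·#{x = y}. The two-sided p is the
  doubled smaller tail of U over all C(n+m, n) labelings of the pooled
  sample (capped at 1) — the enumeration conditions on the pooled values, so
  ties need no correction. Enumeration is used while C(n+m, n) ≤ 200,000;
  beyond that the tie-corrected normal approximation is used and flagged in
  the result. At the 5-vs-5 design the exact test's true size at the 0.05
  level is 8/252 ≈ 0.032, not 0.05 — the discreteness is a property of the
  test, and simulation checks are centred on the exact size.
- **Pearson r**: standard product-moment correlation; requires ≥ 3 paired
  observations and nonzero variance.

## Synthetic data: what it emulates, and what it does not

The generator reproduces, at desk scale, the statistical structure the
analysis assumes: a small set of dense functional modules embedded in a much
larger sparse interactome, seeds concentrated in those modules, and target
sets of controlled breadth. Defaults (all configurable):

- **Graph**: 8 blocks × 40 genes, p_within 0.25, p_between 0.01, plus 2,880
  background genes attached at p_background 2×10⁻⁴. The background makes the
  seed network (≈ 460 genes) a small subnetwork of the ≈ 3,200-gene
  universe, mirroring the real setting where a few-hundred-gene disease
  network sits inside a genome-scale interactome — the regime in which
  per-module enrichment is informative at all. With the blocks alone the
  network would *be* the universe; every per-module test of an evenly-spread
  family would then sit exactly at chance (k/n = K/N) and no breadth signal
  could exist, so the background is a structural requirement, not a tuning
  knob. The attachment probability was set so a background gene has roughly
  a one-in-twenty chance of touching the seed set, keeping the
  network:universe ratio near 15%.
- **Seeds**: 276, drawn from block genes with an optional geometric
  per-block tilt (`seed_block_bias`, default 0 = uniform); optional
  known-absent symbols exercise the unmapped-seed reporting.
- **Families**: 153 of 60 targets each. The *broad* regulator's targets are
  allocated evenly over all 8 blocks (per-block counts differ by ≤ 1); the
  *narrow* regulator keeps the same K by filling its single block to
  capacity (40) and placing the overflow on background genes — real families
  likewise have most targets outside any given network; decoys draw targets
  uniformly (`decoy_target_rate` of each decoy's targets uniform over the
  genome, remainder over block genes).
- **Assays**: ChIP tables (two groups × N = 5 per antibody/region; ZEB
  antibodies carry a planted 2-log2 promoter enrichment over a 1% baseline;
  IgG and control regions carry none) and qPCR tables (planted 2-fold group
  difference, Ct noise sd 0.2, N = 20/group).

Everything is reproducible from `rng_seed` (byte-identical files), and a
self-audit verifies the truth record against the emitted objects on every
generation.

What the generator does **not** emulate: real interactome degree
heterogeneity (hubs), overlapping or nested pathway structure, correlated
target sets among related families, proteomics measurement error in seed
selection, or patient covariates. Passing the recovery tests therefore shows
the pipeline correctly identifies breadth-of-regulation signal when modular
structure exists and targets are (or are not) spread across it — it does not
certify performance on any particular real interactome or TargetScan
release, whose headline counts depend on private resources.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on closed-form fixtures and a scaled-down
scenario (4 blocks × 12 genes, 300-gene universe). The acceptance tests run
the full default scenario over 100 replicate seeds for regulator recovery,
2,000 replicates for the Mann–Whitney null size (n = m = 8, where the exact
size ≈ 0.05), and exhaustive oracles up to N = 20 (hypergeometric) and
8 nodes (modularity). `scripts/acceptance.py` uses 20 recovery replicates —
enough to expose any systematic failure while keeping a single run around
ten seconds.

## Known limitations

- The spanning score's exact historical formula is not published alongside
  the analyses that popularized it; the definition above is this package's
  own, stated prominently and chosen so that breadth dominates. Rankings are
  therefore comparable within `mirspan` runs, not across tools.
- Leading-eigenvector clustering is a greedy heuristic: it can merge or
  split blocks that a global optimizer would not, and `min_module_size`
  trades micro-module noise against resolution.
- Gene identity is by symbol; no alias mapping, no species translation
  beyond the TargetScan species filter.
- The normal-approximation branch of the Mann–Whitney test uses no exact
  mid-p refinement; it is flagged so callers can tell which branch ran.
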
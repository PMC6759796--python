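# Methods

This note records the models, conventions, numerical choices and
limitations behind each module. Nothing here claims an empirical result
that is not computed by the test suite or `scripts/acceptance.py`.

## Target sets and symbols

Gene/protein identifiers are normalized to upper case with surrounding
whitespace and internal hyphens removed (`normalize_symbol`), so
"IL-6" and "il6" collapse to "IL6". Set operations (union across
compounds and source databases, intersection with disease targets) are
performed on the normalized symbols; a `TargetSet` carries a name and
provenance string for reporting.

## Compound–target network

The C–T network is a bipartite graph: compound nodes on one side,
consensus target genes (compound-union ∩ disease list) on the other.
Assertions about the same compound–target pair from several source
databases collapse to a single edge whose `sources` attribute lists the
tags. Compounds with no consensus target drop out of the network, which
is why the node count can be below compounds + targets.

## Topology (NetworkAnalyzer conventions)

Degree, betweenness centrality, average shortest path length (ASPL) and
closeness follow the conventions of Cytoscape's NetworkAnalyzer:

- all shortest-path quantities are computed **within each connected
  component**;
- betweenness of v is the number of shortest (s,t) paths through v,
  divided per pair by the total number of shortest (s,t) paths, and
  normalized by (n−1)(n−2)/2 where **n is the component size** (0 for
  components of fewer than 3 nodes);
- ASPL averages distances from v to the other members of its component;
- closeness = 1 / ASPL (not the sum-of-distances variant);
- isolated nodes get ASPL = NaN, closeness = 0, betweenness = 0.

The per-component betweenness normalization is certified by the fixture:
CYP1A1 sits between AHR and CYP2B6 in a 3-node component and has
betweenness exactly 1 (a whole-graph normalization would give 1/105).
Betweenness is delegated to `networkx.betweenness_centrality` per
component; ASPL uses an in-package BFS. Tests additionally compare both
against a brute-force path-enumeration oracle on all graphs of ≤ 8
nodes drawn from exhaustive classes (paths, cycles, cliques, stars,
complete bipartite, all non-isomorphic trees, random graphs).

Hub extraction: a node is a major hub if its degree is **strictly
greater** than the network's mean number of neighbors (2·E/N over the
whole graph). Ranking is by degree, then betweenness, then node id
(stable mergesort).

## MCODE

Implemented from Bader & Hogue's description:

- **vertex weight** = k × density of the highest k-core of the node's
  closed neighborhood (0 for nodes below `degree_cutoff`, default 2);
- **seeding** in decreasing weight order; **expansion** by breadth-first
  search admitting unassigned neighbors whose weight is at least
  seed_weight × (1 − `node_score_cutoff`), default cutoff 0.2, bounded
  by `max_depth`;
- **post-processing**: clusters without a 2-core are discarded (unless
  fluff is on), optional fluff, then haircut = restrict to the 2-core;
- **score** = density × size, so a clique of n nodes scores n.

The k-core routine is in-package (iterative pruning) and is tested
against both `networkx.k_core` and an exhaustive largest-subset oracle
on graphs of ≤ 10 nodes. Planted-module recovery (a 5-clique in a
sparse 30-node background) succeeds on 20/20 seeds.

On bipartite graphs every closed neighborhood is a star, so vertex
weight reduces to 2/(deg+1): *low*-degree nodes weigh more, and cluster
shapes differ from those on unipartite PPI graphs. The synthetic
generator therefore plants a dense compound-block (several compounds
sharing a target panel, the pattern behind a real formula's
scaffold-family constituents) so that clustering has true structure to
find; recovery of the exact block is not guaranteed, but across seeds
the top cluster's targets are a subset of the planted block's targets
(property-tested over 10 seeds).

## Hub consensus and PPI expansion

Consensus hub targets = topological hubs ∩ top-cluster members
(compound nodes in the cluster cannot match gene symbols and are
inert). PPI edges are kept when score ≥ 0.9 (inclusive, "highest
confidence"). In the resulting graph, nodes are labeled `hub` if they
are consensus hubs and `predicted_functional` otherwise. On the
packaged case-study table this yields 16 nodes / 28 edges, 6 hubs
present, 3 transporters absent (no interaction at that confidence) and
10 predicted functional genes.

## Enrichment

Over-representation uses the hypergeometric distribution: for a query
of n genes in a universe of N, a term with K members and overlap k, the
one-sided p-value is P(X ≥ k) = `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
the two-sided value doubles the smaller tail and caps at 1. Defaults:
α = 0.01 for biological-process terms, α = 0.05 for pathways;
Benjamini–Hochberg adjustment is opt-in (statsmodels). Tests compare
against an exact rational-arithmetic oracle (`Fraction` + `math.comb`)
and verify planted-term recovery and null conservativeness.

## Pharmacokinetics

Simulation: one-compartment oral absorption,
C(t) = F·Dose·ka / (V/F·(ka−ke)) · (e^(−ke·t) − e^(−ka·t)),
defaults ka = 0.05 /min, ke = 0.005 /min, V/F = 20 l/kg, dose
10 mg/kg; noise is mean-one multiplicative lognormal with
σ² = ln(1+CV²), default CV 25%. Times are minutes internally; all
reported parameters are in hours.

NCA: Cmax/Tmax by direct maximum (earliest tie wins); AUC(0–t) by
linear or log-down trapezoid; terminal λz by log-linear regression on
the suffix of strictly-post-peak positive concentrations with the best
adjusted R² (ties favor more points), minimum 3 points; t½ = ln2/λz;
AUC(0–∞) = AUC(0–t) + Clast/λz. Summaries report mean ± sample SD
(ddof = 1; NaN, never 0, for a single subject).

On noiseless profiles with the default 13-point sampling grid, NCA
recovers t½ to ~1e−8 relative error and AUC(0–∞) to 3.7% (linear
trapezoid; log-down reaches 0.7%) — both inside the acceptance bounds
of 2% and 5%. Tmax snaps to the nearest sampling time by construction.

## Synthetic generator fidelity

The generator partitions a 3,000-gene universe into planted-overlap,
disease-only and compound-only pools with a seeded permutation, so
consensus-target and disease-target counts are **exact** (defaults 120
and 812, the case-study scale). Compound target panels are Poisson-sized
draws biased toward planted genes (`planted_weight` = 6) so the C–T
network's edge count lands near the study's (~380–440 vs 446); the
dense block described above supplies cluster structure. Every stream
uses `numpy.random.default_rng` with a derived seed, so all outputs are
pure functions of the seed. Defaults are study conditions, fixed before
outcome checks and not tuned afterwards.

## Limitations

- Only non-compartmental PK is provided; no compartmental fitting.
- MCODE fluff is implemented but off by default and lightly exercised.
- The enrichment model treats annotations as flat sets (no ontology
  hierarchy, no term–term redundancy handling as in ClueGO).
- Betweenness for multi-edges/self-loops is undefined; graphs are
  simplified first.
- The synthetic PPI generator draws independent edges (no degree
  correlation or clustering), which is adequate for filter/threshold
  tests but not for modelling real interactome topology.
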
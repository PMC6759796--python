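# netpharm

A network-pharmacology toolkit for multi-compound preparations, built
around the workflow used to study the herbal formula Qiliqiangxin (QLQX)
in chronic heart failure (CHF): take the targets asserted for every
identified constituent, intersect their union with disease targets,
build and analyze the compound–target (C–T) network, cluster it with
MCODE, derive consensus hub targets, expand them through high-confidence
protein–protein interactions (PPI), test the result for functional
over-representation, and — on the wet-lab side — run non-compartmental
analysis (NCA) on plasma concentration profiles of marker constituents.

The package ships a curated 28-interaction, 16-gene high-confidence PPI
table from the QLQX/CHF case study, a deterministic synthetic-data
generator that reproduces the workflow's statistical shape at full study
scale with known ground truth, a library API, a `netpharm` command-line
tool, and an acceptance script that recomputes every headline quantity.

## The science in one paragraph

A formula with dozens of absorbed constituents acts through a target
*set*, not a single receptor. Each constituent's putative targets are
collected from target databases; their union (here ~1,200 genes) is
intersected with disease-associated genes (~800) to give consensus
targets — genes both druggable by the formula and relevant to the
disease. A bipartite C–T network over those consensus targets is then
mined two ways: topologically (hubs are nodes whose degree exceeds the
network's mean number of neighbors) and structurally (MCODE finds the
densest cluster). Genes found by *both* routes are consensus hub
targets. Restricting a PPI database to its highest confidence tier
(association score ≥ 0.9) around those hubs yields a small subnetwork
whose additional members are predicted functional partners — concrete,
testable hypotheses about the formula's mechanism.

## Worked example

Reproduce the case study's high-confidence PPI analysis from the
packaged fixture (this is `examples/02_network_topology.py` +
`examples/04_hub_consensus_ppi.py`):

```python
from netpharm import fixtures, ppi, topology

hubs = ppi.intersect_hubs(fixtures.MAJOR_TARGETS_32, fixtures.TOP_CLUSTER_17)
g = ppi.build_ppi_network(fixtures.load_fixture_ppi(), hubs)
print(topology.rank_nodes(topology.node_topology(g)).head(4))
```

Actual output:

```
       degree  betweenness  avg_shortest_path_length  closeness
node
VEGFA       7   0.47407407                1.30000000 0.76923077
STAT3       7   0.21481481                1.30000000 0.76923077
EGFR        6   0.08888889                1.40000000 0.71428571
IL6         5   0.05925926                1.50000000 0.66666667
```

and the hub consensus (from `examples/04_hub_consensus_ppi.py`):

```
consensus hub targets (9): ['ATP1A1', 'CYP1A1', 'CYP2B6', 'SLC22A8',
 'SLCO1A2', 'SLCO1B3', 'STAT3', 'STAT4', 'VEGFA']
PPI subnetwork: 16 nodes, 28 edges
hubs present in the subnetwork: ['ATP1A1', 'CYP1A1', 'CYP2B6', 'STAT3', 'STAT4', 'VEGFA']
hubs absent (no interaction at >= 0.9): ['SLC22A8', 'SLCO1A2', 'SLCO1B3']
predicted functional genes (10): ['AHR', 'ATP1B1', 'EGFR', 'FLT1', 'HIF1A',
 'IL6', 'JAK1', 'JAK2', 'KDR', 'NRP2']
```

The metrics follow Cytoscape NetworkAnalyzer conventions: shortest-path
quantities are computed per connected component, betweenness is
normalized by (n−1)(n−2)/2 with n the component size, and closeness is
the reciprocal of the mean shortest path length. The CYP1A1 row
(betweenness exactly 1 inside its 3-node component) pins down the
per-component convention.

## Command line

```
netpharm simulate --out-dir demo --seed 1      # write a synthetic input set + config.yaml
netpharm run --config demo/config.yaml         # run every stage, write results + manifest
netpharm ppi --min-score 0.9 --out f.tsv --sif f.sif   # filter the packaged PPI table
netpharm topology --sif f.sif --out topo.tsv
netpharm nca --input conc.csv --out nca.tsv
```

`netpharm run` writes, per stage: consensus target list, C–T network
(SIF + GraphML), topology table, MCODE clusters, consensus hub targets,
filtered PPI network and its topology, enrichment tables, NCA summary,
and a `manifest.json` recording input hashes, parameters and every
count.

## Synthetic data with known truth

Raw study inputs (database exports, plasma concentrations) are not
redistributable, so `netpharm.synthetic` generates datasets with the
same statistical shape and *exact* planted ground truth: the
compound-target union intersects the disease list in precisely
`planted_overlap` genes (default 120 of 812, matching the study scale),
a dense compound–target block plays the role of the real data's
top MCODE cluster, PK profiles come from a one-compartment oral model
with known half-life, and one annotation term is planted to be
enriched. Every generator is a pure function of its seed.

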
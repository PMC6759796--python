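"""Consensus hub targets and the high-confidence PPI subnetwork.

Intersects the 32 topological hub targets of the case-study C-T network
with the 17-node top MCODE cluster, yielding 9 consensus hub targets.
Filtering the packaged interaction table at association score >= 0.9
gives a 16-node subnetwork containing 6 of those hubs plus 10 predicted
functional partners; the 3 solute-carrier transporters have no
interaction at that confidence and drop out.
"""

from netpharm import fixtures, ppi

hubs = ppi.intersect_hubs(fixtures.MAJOR_TARGETS_32, fixtures.TOP_CLUSTER_17)
print(f"consensus hub targets ({len(hubs)}):", sorted(hubs))

edges = ppi.filter_ppi_edges(fixtures.load_fixture_ppi(), ppi.HIGHEST_CONFIDENCE)
g = ppi.build_ppi_network(edges, hubs)
report = ppi.make_hub_report(fixtures.MAJOR_TARGETS_32,
                             fixtures.TOP_CLUSTER_17, g.nodes())

print(f"\nPPI subnetwork: {g.number_of_nodes()} nodes, "
      f"{g.number_of_edges()} edges")
print("hubs present in the subnetwork:",
      sorted(report.consensus & set(g.nodes())))
print("hubs absent (no interaction at >= 0.9):",
      sorted(report.consensus - set(g.nodes())))
print(f"predicted functional genes ({len(report.predicted_functional)}):",
      sorted(report.predicted_functional))
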
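"""Export the pathway-level result graph for an external viewer.

After an enrichment run, pathways become nodes (carrying statistic, p-value,
q-value and a significance flag) and two pathways are connected when at
least one gene of one interacts with at least one gene of the other; the
graph and its significant-only subgraph (here at an illustrative FDR cut of
0.1) are written as GraphML.
"""

import pynetgsa as pg

design = pg.SimulationDesign(
    p=60, n_components=2, n_pathways=8, edge_density=0.1, seed=7)
adj, adjset = pg.generate_network(design)
pathways = pg.generate_pathways(design)
data = pg.generate_expression(
    adjset, None, 0.3, 0.7, {"cond1": 40, "cond2": 40}, seed=8)
dys = pg.select_dysregulated(adj, "neighborhood-seeded", 0.25, seed=9)
data = pg.standardize_and_dysregulate(data, dys, 0.4, "cond2")
results = pg.run_netgsa(data, pathways, edges=adj, seed=1)

graph = pg.build_pathway_graph(results, pathways, adj, fdr_cut=0.1)
pg.export_graphml(graph, "pathway_graph.graphml")
sig = pg.subgraph_significant(graph)
pg.export_graphml(sig, "pathway_graph_significant.graphml")
print(f"full graph: {graph.number_of_nodes()} pathways, "
      f"{graph.number_of_edges()} between-pathway connections")
print(f"significant subgraph: {sig.number_of_nodes()} pathways, "
      f"{sig.number_of_edges()} connections")
print("wrote pathway_graph.graphml and pathway_graph_significant.graphml; "
      "node colors in a viewer can map 'stat' and 'qvalue'.")
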
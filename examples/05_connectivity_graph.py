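"""Build and export the intra-cluster connectivity graph of one module.

Within a consensus cluster an edge joins two genes whose dependency
profiles correlate at Spearman rho > 0.1; the resulting graph shows which
cluster members are directly co-dependent and which are linked only
through a shared hub.
"""

from depmix import (align_screens, combine_scores, connectivity_graph,
                    default_screen_spec, edge_list, export_graphml,
                    generate_paired_screens, impute_cross_method,
                    sample_info_table)

spec = default_screen_spec()
crispr, shrna, truth = generate_paired_screens(spec)
ca, sa, _ = align_screens(crispr, shrna, sample_info_table(spec))
ci, ri = impute_cross_method(ca, sa, seed=1)
combined = combine_scores(ci, ri, 0.6)

members = truth.module_members(0)
graph = connectivity_graph(members, combined, rho_min=0.1)
print(f"module 0: {graph.number_of_nodes()} genes, "
      f"{graph.number_of_edges()} edges at rho > 0.1")

edges = edge_list(graph)
print("strongest co-dependencies:")
print(edges.head(5).to_string(index=False))

export_graphml(graph, "module0.graphml")
print("wrote module0.graphml (open in Cytoscape/Gephi)")
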
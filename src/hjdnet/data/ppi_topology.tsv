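parameter	value
clustering_coefficient	0.667
connected_components	1
network_diameter	4
network_radius	2
network_centralization	0.474
shortest_paths	9506
characteristic_path_length	2.006
avg_neighbors	20.959
n_nodes	98
n_edges	1027
network_density	0.216
network_heterogeneity	0.676
isolated_nodes	0
self_loops	0
multiedge_pairs	0
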
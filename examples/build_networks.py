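"""Build a mutual-kNN co-expression network matched in size to a given
interaction network.

Two genes are linked when each ranks the other among its top-k most
correlated partners; k is chosen as the smallest value whose edge count
reaches the interaction network's, so the two graphs are comparable.
"""

from netfeat import (
    CoexpressionConfig,
    build_mutual_knn,
    choose_k_for_edge_count,
    degree_summary,
    generate_study,
    SimulationConfig,
)

study = generate_study(SimulationConfig(n_genes=300, cohorts=(("c1", 100, 200),), seed=3))
ppi = study.true_network  # stands in for a curated interaction network

report = choose_k_for_edge_count(study.dataset, target_edges=ppi.n_edges)
print(f"target {report.target_edges} edges -> k={report.k} "
      f"({report.edges_below_k} edges at k-1, {report.edges_at_k} at k)")

ce = build_mutual_knn(study.dataset, CoexpressionConfig(k=report.k))
print(f"co-expression network: {ce.n_edges} edges over {ce.n_nodes} genes")
print(f"interaction network:   {ppi.n_edges} edges over {ppi.n_nodes} genes")

for name, net in (("co-expression", ce), ("interaction", ppi)):
    s = degree_summary(net)
    print(f"{name}: mean degree {s.mean_degree:.2f}, median {s.median_degree:.0f}")
print("\nMean degree is 2E/N; matched edge counts make the feature universes"
      "\nof the two network contexts the same size.")
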
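"""Compute all 15 feature types and count how many separate the outcome
classes after FDR correction.

Node-based features summarize a gene's geneset (the gene plus its network
neighbors) per patient with one operator — mean, max, min, median,
variance, or neighbors-only mean; edge features sum the two endpoint
expressions. Each feature is screened with Student's t-test and the
Benjamini-Hochberg adjustment at FDR 0.1.
"""

from netfeat import (
    FEATURE_TYPE_NAMES,
    SignificanceConfig,
    SimulationConfig,
    compute_features,
    compute_significance,
    count_significant,
    generate_study,
    build_mutual_knn,
    CoexpressionConfig,
)

study = generate_study(SimulationConfig(cohorts=(("c1", 150, 300),), seed=5))
networks = {
    "CE": build_mutual_knn(study.dataset, CoexpressionConfig(k=9)),
    "PPI": study.true_network,
}
labels = study.dataset.outcome.to_numpy()
config = SignificanceConfig(fdr_threshold=0.1)

print(f"{'type':8s} {'features':>9s} {'significant':>12s}")
for name in FEATURE_TYPE_NAMES:
    net = None if name == "Gene" else networks["CE" if name.startswith("CE") else "PPI"]
    fm = compute_features(study.dataset, name, net)
    table = compute_significance(fm, labels)
    print(f"{name:8s} {fm.n_features:9d} {count_significant(table, config):12d}")

print("\nAggregating over genesets concentrates weak per-gene signal, so"
      "\nMEAN-style network features pass the threshold more often than raw"
      "\ngenes; edge types have far larger feature universes.")
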
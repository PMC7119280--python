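"""Generate a synthetic multi-cohort expression study and inspect it.

The generator plants co-regulated gene modules (cliques in the true
network), shifts the latent activity of a few modules between poor- and
good-outcome patients, and adds per-cohort batch offsets. The 12-cohort
layout mirrors a well-known breast-cancer compendium's sizes and class
imbalance, scaled down here for speed.
"""

import pandas as pd

from netfeat import generate_multi_cohort_study

study = generate_multi_cohort_study(scale=0.25, seed=7)
dataset = study.dataset

print(f"{dataset.n_genes} genes x {dataset.n_patients} patients, "
      f"{len(set(dataset.cohort))} cohorts")
print(f"true network: {study.true_network.n_edges} within-module edges")
print(f"{len(study.differential_genes)} genes carry class signal\n")

counts = (
    pd.DataFrame({"cohort": dataset.cohort, "outcome": dataset.outcome})
    .groupby("cohort")["outcome"]
    .agg(poor="sum", total="count")
)
counts["good"] = counts["total"] - counts["poor"]
print(counts[["poor", "good", "total"]].to_string())
print("\nEach row is one study: class imbalance varies across cohorts, as in"
      "\nreal compendia, which is what makes per-cohort screening unstable.")
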
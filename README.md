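# netfeat

Network-based gene-expression features for binary outcome prediction, built
for the question that motivates them in cancer prognosis: does integrating a
gene network with expression profiling actually buy prediction accuracy and
signature stability, and under which sample sizes?

`netfeat` is a library for systems-biology practitioners who have a
log-normalized genes × patients expression matrix, a binary phenotype
(e.g. metastasis within 5 years: *poor* vs *good* outcome), and optionally a
protein–protein interaction (PPI) edge list. It provides, end to end:

- **Networks** — a mutual k-nearest-neighbor co-expression graph (genes *g*,
  *h* linked iff each ranks the other in its top-*k* by Pearson correlation),
  with *k* selectable to match the PPI network's edge count; PPI edge-list
  ingest with self-edge removal and gene-universe restriction.
- **15 feature types** — per patient, an operator over each *geneset* (a gene
  and its network neighbors): MEAN, MAX, MIN, MED, VAR (population),
  neighbors-only mean (NO), per-edge endpoint sums (Edge), each crossed with
  the co-expression (CE) or PPI context, plus the raw Gene baseline.
- **Screening** — per-feature Student's (pooled-variance) t-test between
  outcome groups and Benjamini–Hochberg FDR adjustment at threshold 0.1.
- **Robustness** — each cohort's top-160 features reduced to a 160-gene
  signature (edge types pool endpoint genes in rank order); every cohort pair
  scored by observed/expected overlap where the null expectation is
  k²/N (160²/12,750 ≈ 2 in the motivating compendium); geometric-mean fold
  change over all pairs, with hub-bias degree diagnostics.
- **Evaluation** — L2-regularized logistic regression under repeated
  stratified 5-fold cross-validation scored by AUC (rank-statistic
  definition, ties at 0.5), with no feature selection; the **CNF** ensemble
  (Combined Network Features) averaging predicted probabilities of the eight
  MEAN/MAX/MIN/MED × CE/PPI models on shared fold splits; and subsample
  learning curves (90% down to 10%, stratified draws).
- **Synthetic studies** — a generator planting modular co-expression
  structure, weak per-gene class signal distributed over module latent
  activities, cohort batch effects, and a 12-cohort layout mirroring a real
  breast-cancer compendium (455 poor / 1,161 good / 1,616 patients), with
  ground truth for every claim the pipeline makes.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/evaluate_cnf.py` simulates a 900-patient study with
module-distributed signal, builds the co-expression network, and compares
cross-validated AUCs:

```
Gene     mean AUC 0.750 over 15 fold evaluations
CEMEAN   mean AUC 0.848 over 15 fold evaluations
PPIMEAN  mean AUC 0.848 over 15 fold evaluations
CNF      mean AUC 0.850 over 15 fold evaluations
```

Raw gene features reach 0.75 because each gene carries only a weak slice of
the module-level signal; averaging each geneset (CEMEAN/PPIMEAN) recovers
the latent module activity and lifts AUC by ~0.10, and the CNF probability
average edges out every single component. `python examples/screen_features.py`
shows the same mechanism at the screening stage (130 significant CEMEAN
features vs 53 significant genes at FDR 0.1), and
`python examples/robustness_across_cohorts.py` shows that top-gene signatures
of *small* cohorts overlap barely above the k²/N random expectation (fold
change ≈ 1), the package's robustness caveat.

A thin CLI mirrors the stages (`netfeat simulate | build-network | features |
significance | robustness | evaluate | cnf | subsample | pipeline`); the
`pipeline` subcommand runs everything from one YAML config and writes a
manifest of SHA-256-checksummed outputs.

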
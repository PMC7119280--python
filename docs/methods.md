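# Methods

This note documents the models, conventions, and design choices behind
`netfeat`, in the order the pipeline runs.

## Data model and input conventions

Expression is a genes × patients matrix of unitless log-scale values,
assumed log-normalized and mean-centered upstream; the reader warns (never
errors) when the global mean deviates from 0 by more than a configurable
tolerance (default 0.05), because centering is a preprocessing concern
outside this package's scope. Missing or non-finite values are rejected
rather than imputed: the pipeline's statistics (correlation ranks,
pooled-variance t-tests) have no principled missing-data story, and silent
imputation would distort geneset aggregates. Outcomes are binary
(poor = 1, good = 0) and every patient carries a cohort id; all files are
TSV with opaque string gene ids.

## Co-expression network

The mutual k-nearest-neighbor graph links genes *g*, *h* iff each is within
the other's top-*k* by Pearson correlation computed on all cohorts pooled.
Conventions:

- **Ranking** is by *signed* correlation by default — "most co-expressed"
  is read as positive co-expression. Absolute-value ranking is available
  (`ranking="absolute"`) for users who consider strong negative
  co-regulation equally informative; the choice is recorded in network
  provenance.
- **Ties** at the k-th rank are broken by lexicographic gene id after
  sorting by correlation descending, making the graph a deterministic
  function of the data.
- **k selection**: given a target edge count (typically the PPI network's),
  the package returns the *smallest* k whose mutual-kNN edge count meets or
  exceeds the target, together with the counts at k and k−1. Edge count is
  nondecreasing in k (an edge that is mutual at k stays mutual at k+1), so
  the search is well defined; smallest-k-reaching-target is preferred over
  nearest-count because it is a simpler, deterministic contract.
- Zero-variance genes make Pearson correlation undefined and raise an error
  naming the gene; with fewer than 3 patients correlation ranks are
  meaningless and construction refuses to run.

Internally the builder computes a full neighbor-rank matrix and takes
`max(rank[i,j], rank[j,i]) <= k`, which is algebraically identical to
intersecting the two top-k lists; an independent brute-force oracle in the
test suite confirms equivalence on random instances.

## Feature types

A *geneset* is a gene plus its direct neighbors in one network. Per patient
and per gene: MEAN/MAX/MIN/MED/VAR over the geneset values, NO (mean over
neighbors only), and per network edge the sum of its two endpoint values.
Conventions where the definitions are silent:

- **VAR** is the population variance (denominator = geneset size), so a
  singleton geneset has VAR exactly 0 rather than an undefined value.
- **Median** of an even-sized geneset is the mean of the two central values.
- **NO for isolated genes** falls back to the gene's own expression. Some
  defined value is required — real PPI networks leave many genes isolated,
  and dropping or zeroing them would misalign feature universes across
  cohorts and produce constant features; the gene's own value is the least
  surprising proxy for its (empty) neighborhood.
- Feature ids are gene ids for node-based types and `geneA|geneB` with
  sorted endpoints for edge types; rows are emitted in sorted id order so
  outputs diff cleanly.

Each feature records provenance ({gene} ∪ neighbors, or the two endpoints),
which the robustness stage consumes.

## Significance screening

Each feature is tested with the classical equal-variance two-sample t-test
(p from the t distribution with n₁+n₂−2 df). Constant features receive
p = 1 with a warning instead of being dropped, keeping universes aligned
across cohorts. Benjamini–Hochberg step-up adjustment (via statsmodels)
gates significance counts at FDR threshold 0.1; *ranking* for signature
selection uses raw p-values with lexicographic tie-break, because selection
order, not error control, is what ranking feeds.

## Robustness across cohorts

Per cohort, the top-160 features become a 160-gene signature: node-based
types map one feature to its gene; edge types walk edges in rank order,
inserting endpoint genes into an insertion-ordered set, stopping once 160
genes are reached and truncating to the first 160. (Truncation in insertion
order — rather than re-ranking the pooled genes — keeps the signature a
prefix of the edge ranking.) For each cohort pair, observed overlap is
compared to the expectation k²/N for two independent k-of-N draws (the
hypergeometric mean); the expected value is kept at full precision.
A zero observed overlap is replaced by a pseudocount of 0.5 (configurable)
before the ratio so that log-scale summaries remain finite; the summary is
the geometric mean of fold changes over all C(c,2) pairs. Degree
diagnostics (mean/median degree of each signature in the relevant network)
expose size-biased hub selection: genes on many edges enter edge-pooled
signatures disproportionately often, inflating apparent overlap with no
biological stability behind it.

## Classification and the CNF ensemble

Each feature matrix is evaluated with repeated stratified k-fold
cross-validation (defaults: 5 folds × 10 repetitions) and AUC — the
probability that a random poor-outcome patient outranks a random good one,
ties at 0.5 — appropriate under class imbalance. Numerical choices:

- **L2-regularized logistic regression** (inverse strength C = 1.0, lbfgs,
  max 1000 iterations): with features ≫ patients an unpenalized fit is
  ill-posed, and a fixed ridge penalty keeps every feature type on the same
  footing without hyperparameter search.
- **Within-fold z-score standardization**, fit on training patients only:
  VAR and Edge features live on very different scales, and a shared scale
  makes the penalty comparable across types. The training-only contract is
  property-tested (perturbing a held-out patient never changes the model).
- **Stratified folds**: small imbalanced cohorts would otherwise produce
  single-class folds, for which AUC is undefined.
- **No feature selection anywhere** — the comparison is between feature
  *constructions*, and supervised selection would confound it.

CNF fits one logistic model per component type (MEAN, MAX, MIN, MED for
both CE and PPI networks — eight models) on *identical* fold splits within
a repetition and averages their predicted probabilities per held-out
patient; sharing splits is required for the per-patient average to be well
defined. Fold splits derive from the master seed via `SeedSequence`, so
every AUC is reproducible bit for bit.

The subsample experiment draws class-stratified subsets without replacement
(class counts rounded to the nearest patient) at percentages 90% … 10%,
10 draws per level by default, and reruns the full CV per draw.

## Synthetic study generator

The generator emulates the statistical structure the pipeline assumes, not
microarray physics. Genes come in modules of `module_size` (default 10);
each patient draws a unit-normal latent activity per module; a configurable
number of modules (default 10 of 50) are *differential*: their latent mean
shifts by ±δ/2 with class (δ = `effect_size`, default 0.5 latent-SD). A
gene's value is `gene_loading` (λ, default 0.6) times its module activity,
plus a per-cohort per-gene batch offset (SD 0.3) and unit residual noise,
then per-gene mean-centered. The defaults put the data in the weak-per-gene,
distributed-signal regime (per-gene Cohen's d ≈ 0.26, module-aggregated
d ≈ 0.44) — the regime in which geneset aggregation genuinely helps, which
is the scientific premise under study; a pilot confirmed gene-level AUC sits
well below ceiling there. The true network is the union of within-module
cliques, so feature-engine correctness can be tested without network-
inference noise; recovering the modules by mutual-kNN is a separate tested
path. A `single_gene` mode instead plants the shift directly on one carrier
gene per differential module, generating the opposite regime in which
neighborhood aggregation dilutes signal. The 12-cohort layout reproduces a
real compendium's per-study (poor, good) counts (455/1,161/1,616 total) and
scales by a factor with per-cohort rounding (floored at one patient per
class). All randomness flows from one master seed through `SeedSequence`
stream-splitting.

What the generator does *not* emulate: probe-level artifacts, heavy-tailed
noise, correlated batch-by-class confounding, survival censoring, or
realistic PPI topology (cliques are more regular than scale-free
interactomes — the degree-bias diagnostic is therefore exercised on
preferential-attachment graphs in the tests). Passing tests on this
generator show the pipeline's statistics behave as designed under its
stated assumptions, not that any particular biological dataset satisfies
those assumptions.

## Problem sizes in tests and the acceptance script

The shipped checks use deliberately modest sizes chosen as the package's
own desk-scale defaults: 500-gene studies with n = 1,200 patients and 3 CV
repetitions for the Gene-vs-CNF comparison, single-repetition CV with 3
draws per level for the subsample trend, 100 null runs of 2,000 features ×
300 patients for the FDR control check, and brute-force oracle sweeps up to
25 genes. The null-control runs use a single balanced cohort with zero
batch SD: with unequal class ratios across cohorts, a cohort-level batch
offset correlates with class and the data would no longer be null — a
property of the construction, not a tuning choice.

## Known limitations

- Pearson correlation on pooled cohorts conflates within- and
  between-cohort co-expression; a cohort-stratified correlation is not
  implemented.
- The logistic models are not calibrated; CNF averages raw predicted
  probabilities, which is standard but sensitive to component
  miscalibration.
- The robustness statistic compares signatures of exactly equal size; it
  has no notion of partial credit for near-miss genes (e.g. network
  neighbors of overlapping genes).
- Degree-0 NO features equal Gene features by construction; on networks
  with many isolated genes the NO type partially duplicates the baseline.
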
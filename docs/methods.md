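# Methods

## The component model

A task is a declared API plus three component lists. Dataset generators
have the signature `fn(test_mode, seed) -> CellByGeneDataset`; in test
mode they must return at most 500 cells so a full benchmark stays
interactive. Methods map a dataset to a dataset with output slots
filled; metrics map that to one float with a declared orientation.
Methods carry a role: ordinary `method`, or `positive_control` /
`negative_control`. Controls are ordinary methods that may read the
ground-truth store; all other methods must not (the matching task
strips the pairing from the working copy before a non-control method
runs, and each task's `api_check` validates the contract before and
after every method).

The runner executes every method on every dataset and every metric on
every result. A raising method records missing values for all its
metrics on that dataset with a logged diagnostic — a living benchmark
must survive one bad contribution — and the spatial task deliberately
ships one such method (`de_novo`, unimplemented pending a
factor-to-type matching rule) to keep that path exercised. Resources
(wall clock, peak RSS) are recorded but never scored.

## Score normalization and ranking

Per (dataset, metric), minimize-oriented values are negated, the best
and worst oriented scores *among controls* define the anchors, and all
methods map through `(x − worst)/(best − worst)`. Values are not
clipped; scores below 0 are meaningful ("worse than random", e.g. R²
of a bad regressor). Degenerate anchors (equal or missing control
scores) leave that column missing with a warning rather than producing
NaNs that would poison averages. Overall score is the mean of a
method's non-missing normalized scores on a dataset; a method with no
scores ranks last rather than disappearing, keeping tables
rectangular. Ranks use competition ranking (1, 2, 2, 4). Cross-subtask
collation (used for the two communication subtasks) is the unweighted
mean of per-subtask overall scores over the subtasks where a method
ran, flagged when coverage is partial.

Maturity thresholds: stub at ≥ 1 dataset / 3 methods / 1 metric, full
at ≥ 2 / 6 / 1. Control methods count toward the tallies; with one
synthetic dataset variant per task (two for label projection) and a
deliberately small method roster, every shipped task classifies as a
stub.

## The data container

`CellByGeneDataset` holds non-negative integer UMI counts, per-cell and
per-gene metadata, named layers (counts-shaped), embeddings, cell-cell
graphs, and a free-form truth store. Serialization: h5ad via `anndata`
(X/obs/var/layers/obsm/obsp), or a plain-text Matrix Market directory
(genes-as-rows on disk, transposed on read, CSV metadata). The truth
store is serialized through one tagged-JSON codec in both dialects so
arrays, frames and scalars round-trip exactly. Counts are stored sparse
below 50% density, dense otherwise — purely a storage choice.

log-10k is the shared normalization: each cell scaled to 10,000 total
counts, then `log1p` (natural log; the dominant single-cell
convention). All-zero cells map to zero rows instead of raising so
degenerate inputs flow through pipelines. Task harnesses compute the
log-10k layer once and hand the same matrix to methods and metrics;
methods may not renormalize, which removes a known source of metric
bias.

## Synthetic data

The generators produce the statistical structure each evaluation
assumes, not a full emulation of platform noise (no ambient RNA,
doublets, or zero inflation — the latter is an extension point,
default off).

**Cell-type counts.** Gamma-Poisson: baseline gene means are
log-normal(0, 1); each of `n_types` types multiplies a `de_fraction`
subset of genes by log-normal(0, `de_strength`) fold changes; profiles
are renormalized to sum 1; per-cell library sizes are
gamma(`library_size_shape`, mean `library_size_mean`); counts are
Poisson(library × profile). Defaults — 2,000 cells, 500 genes, 4
types, 10% DE genes at sd 1, libraries averaging 2,000 UMIs with shape
2 — describe a small droplet experiment with clearly separable types:
a default-regularized logistic regression reaches > 0.9 held-out
accuracy, which is what the label-projection evaluation needs.
Test-mode datasets are capped at 300 cells × 120 genes with 1,000-UMI
libraries.

**Batch effects.** Cells are assigned to batches round-robin within
each type (so per-batch type frequencies are flat and the
perfect-embedding control is well defined); per-(batch, gene)
multiplicative log-normal(0, `batch_strength`) factors scale the count
means, and counts are Poisson-resampled around the scaled means to
stay integer. Strength 0 short-circuits to the untouched counts. At
the default strength 1, a k-NN graph on log-10k PCs shows a clear
same-batch neighbor excess — there is a real effect to remove.

**Spatial mixtures.** Per spot: proportions ~ symmetric
Dirichlet(α = 1 by default), cell count ~ Poisson(mean 20, min 1),
cells sampled with replacement per type from the reference, spot counts
= sum of sampled cells' counts. The truth stores the Dirichlet draws;
at finite cells per spot the realized composition differs by
multinomial noise, which is why recovery is tested near the deep-spot
limit (200 cells/spot).

**Paired modalities.** A shared standard-normal latent (d = 10) maps
linearly into each view (defaults 100 and 80 features, noise sd 0.1);
the first 40 columns of both views use the same map — a shared feature
block that the alignment method may exploit. Counts are an all-zero
placeholder; the real-valued views live in `layers["data"]`. This tests
the evaluation geometry of modality matching, not count statistics.

**Planted communication.** (source type, target type, ligand-receptor
pair) triples are drawn uniformly without replacement from the
5-type × 50-pair combination space (5 types rather than the global
default 4, so the source-target ranking has ≥ 20 keys, the odds-ratio
metric's minimum); the ligand's counts in source cells and the
receptor's in target cells are scaled 20-fold by Poisson resampling.
The planted truths preserve the two evaluation levels (source-target
and ligand-target) of real colocalization/cytokine ground truths, not
their biology.

## Task-specific choices

* **Label projection** — logistic regression uses fixed C = 1 (no
  hyperparameter search: the benchmark measures defaults); k-NN votes
  over k = 15 neighbors in top-50 PC space with ties broken toward the
  lexicographically smallest label. Query-only labels are allowed and
  count as errors (zero recall in macro-F1).
* **Denoising** — MCV with `p_train` = 0.9 keeps 90% of molecules as
  signal while leaving a usable test sample. Denoised output is scaled
  by (1 − p)/p before comparison (binomial-thinning expectation
  matching); the Poisson loss adds ε = 1e-6 inside the log so zero
  predictions are admissible. The positive control is the rescaled
  test layer itself — the best attainable predictor given the split.
  Known behavior: with a 10%-depth test layer the log-scale MSE
  rewards sparse predictions, so the dense k-NN average scores
  slightly below identity on MSE while clearly beating it on Poisson
  loss.
* **Dimensionality reduction** — the positive control passes the full
  log-10k matrix to the metrics, an explicit exemption from the 2D
  contract that bounds achievable scores. Spectral embedding grows k
  internally (with a warning) if the neighbor graph is disconnected.
  Distance correlation subsamples to ≤ 1,000 cells with a fixed
  internal seed so the metric stays a pure function of its input;
  Spearman uses average ranks on ties.
* **Batch integration** — outputs convert down the chain matrix →
  embedding (top-30 PCs) → graph (symmetrized 15-NN), so the two
  metrics evaluate all three output formats. The positive control
  (one-hot cell types + 0.01 jitter) maximizes both mixing and
  conservation simultaneously only because batch assignment is
  stratified by type — an idealization, stated here. Silhouette
  follows the convention that singleton clusters contribute 0.
* **Spatial decomposition** — joint-entry R² (one number, no undefined
  per-type variance cases) about the global truth mean, plus MAE.
  All-zero NNLS solutions fall back to a uniform row with a warning.
* **Matching modalities** — FOSCTTM uses the (n − 1) denominator
  (true match excluded from candidates) so 0 is perfect and the fully
  adversarial arrangement scores exactly 1; strict inequality means
  ties favor the method.
* **Cell-cell communication** — magnitude score is the mean of the
  ligand's source-type and the receptor's target-type mean log-10k
  expression, gated to 0 below 10% detection (CellPhoneDB-style).
  Specificity permutes labels 100 times and reports
  1 − (r + 1)/(n_perm + 1) with r the count of null scores ≥ observed.
  AUPRC is the stepwise precision-recall walk with absent positives
  counted as never retrieved; the odds ratio uses the top
  ceil(0.05 n) bin with the Haldane-Anscombe +0.5 correction whenever
  a contingency cell is zero. Aggregation ties break lexicographically
  so rankings are deterministic.

## What passing tests do and do not show

The suite verifies the framework's guarantees (anchoring, isolation,
reproducibility, serialization), the metric implementations against
independent oracles (brute-force trustworthiness, sklearn average
precision, closed-form NNLS on orthogonal designs), and parameter
recovery under the generators' assumptions. It does not show that the
shipped methods are competitive on real data: the generators' clean
gamma-Poisson structure, flat type abundances, and linear batch/latent
effects are deliberately easier than real tissue. Problem sizes in the
default test run (≤ 300-cell test-mode datasets; 2,000 × 500 for the
recovery checks; 10 replicates for the aggregation-tendency check) are
the package's chosen desk scale.
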
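# Methods

This note documents the models and estimators implemented in `scqc`, the
design choices made where several defensible options existed, what the
synthetic data generator does and does not emulate, and the toolkit's
known limitations.

## Data model

A `QCExperiment` holds one sparse non-negative integer gene × barcode
matrix with unique identifiers on both axes, per-cell and per-gene
annotation tables, named embeddings, same-shaped extra assays, and a
provenance log. Genes are rows and barcodes columns throughout; exporters
transpose where a format demands it (h5ad stores cells × genes).

Matrix levels encode filtering state, not count processing: `Droplet`
(all barcodes), `Cell` (empty droplets removed), `FilteredCell`
(poor-quality cells also removed). A level only ever advances, and only by
column subsetting, so counts of retained barcodes are immutable by
construction. Multi-sample experiments carry a mandatory `sample`
annotation; every QC algorithm is applied within each sample
independently, and results on a combined experiment equal per-sample
results concatenated.

Reproducibility: a single pipeline seed is mapped to per-operation,
per-sample seeds via SHA-256 of `"<seed>:<operation>"` (mod 2^31).
Adding or removing one operation therefore does not perturb the seeds of
the others. Every operation appends one provenance entry (name, parameter
map, seed, timestamp, version), serialised as YAML with the flat-file
export and into `uns` of the h5ad export.

## Empty-droplet detection

**Barcode ranks.** Barcodes are ranked by descending total count (ties
share the average rank). On the unique-value (log10 rank, log10 total)
curve above `lower`, a cubic smoothing spline (generalised cross-validated
smoothing) is fit and the knee is taken at the minimum of the signed
curvature y''/(1+y'²)^{3/2}; the inflection is the steepest-descent point
of the raw unique curve at or beyond the knee, floored at `lower` and
capped at the knee. With fewer than five unique totals, discrete
differences replace the spline; a flat curve degenerates to knee =
inflection = the common count. The knee of a curvature-minimum estimator
sits at the upper shoulder of the cliff separating cells from empties —
above the cliff's geometric midpoint — while the inflection sits mid-cliff;
both thresholds separate the two plateaus, which is what filtering uses
them for.

**Ambient profile.** Counts over all barcodes with total ≤ `lower`
(default 100 — a convention, exposed as a parameter; a typical cell has
hundreds to thousands of UMIs and ambient barcodes tens) are pooled,
a pseudo-count of 0.5 per gene is added, and the vector is normalised.

**Monte-Carlo test.** For each barcode with total > `lower` the
multinomial log-likelihood of its counts under the ambient profile,
conditioned on its total, is compared against `n_iters` (default 10,000)
simulated ambient droplets at the same total. The p-value uses the
add-one estimator (1+b)/(1+n) so it is never zero; `limited` records
b = 0 (more iterations could lower the p-value). The simulation is
stratified by total and computed incrementally: `n_iters` null droplets
are grown item by item from the ambient distribution, and every snapshot
at a tested total is an exact Multinomial(total, ambient) draw. This
costs O(max_total × n_iters) regardless of how many distinct totals are
tested; increments larger than twice the gene count use a bulk
multinomial draw instead of the item loop. Correctness of the stratified
p-values is verified in the test suite against exhaustive enumeration on
a 3-gene instance, and their null calibration by KS test on data drawn
from the ambient model.

Multiplicity is handled by Benjamini–Hochberg over tested barcodes only;
the cell call is `q ≤ fdr` (default 0.01, logged) OR `total ≥ retain`,
where `retain` defaults to the barcode-rank knee so unusually large cells
are never discarded; calibration experiments disable it.

## Per-cell metrics and outlier flagging

Totals, detected genes, the percentage of the library occupied by the top
N expressed genes (N ∈ {50, 100, 200, 500}, the conventional grid,
configurable), and per-gene-set count percentages. Gene-set matching is
exact string match after stripping Ensembl version suffixes; mitochondrial
sets for human and mouse ship in symbol/Ensembl/Entrez form. Empty cells
use the 0/0 := 0 convention; a gene set matching nothing yields zeros
with a warning. A dual-route test checks these metrics against scanpy's
independent implementation.

Outlier flagging uses the median ± nmads × MAD rule (MAD scaled by 1.4826
for normal consistency; nmads default 3), per sample, by default on
log2(x+1) — QC metrics are right-skewed, and the log scale keeps the MAD
meaningful; this default is recorded in provenance. Zero MAD flags
nothing (with a warning) rather than everything.

## Doublet detection

Artificial doublets are sums of the raw counts of uniformly sampled
distinct cell pairs (no library-size matching — real doublets sum two
libraries too). Feature space for the kNN and classifier scorers:
counts-per-10k, log1p, top 2,000 variable genes by log-scale variance,
PCA to 30 components.

* **kNN score.** Observed cells and `sim_ratio`·n simulated doublets are
  embedded jointly; with q the fraction of simulated doublets among a
  cell's k = √n nearest neighbours and r the simulated fraction of the
  pool, the score q(1−r)/(q(1−r)+(1−q)r) estimates the probability that
  the cell's neighbourhood is doublet-dominated.
* **cxds.** Genes are binarised at their per-gene median count (which
  reduces to "detected" for genes expressed in under half the cells);
  among the 500 most variable binarised genes, each pair is scored by the
  z-statistic of its co-expression deficit relative to independence, and
  a cell's score sums the statistics of the top 500 pairs it co-expresses.
  Mutually exclusive marker pairs are doublet witnesses. Deterministic.
* **bcds.** An XGBoost classifier (100 trees, depth 4, single-threaded
  for determinism) discriminates observed cells (label 0) from simulated
  doublets (label 1); observed cells are scored by out-of-fold predicted
  probability under 3-fold stratified CV.
* **Hybrid** is the sum of min-max-normalised cxds and bcds scores
  (range [0, 2]); **consensus** calls cells flagged by ≥ `min_votes`
  (default 2) algorithms.

**Threshold.** Scores are thresholded at the minimum-density valley of a
Gaussian KDE between the main (singlet) mode and the right-most secondary
mode, falling back to the (1 − expected_rate) quantile (expected_rate
default 0.05) when no usable second mode exists or a majority of cells
would be called. A two-component Gaussian mixture boundary was evaluated
first and systematically over-called on scores with a heavy inter-modal
bridge; the valley rule tracks the simulated 10% truth closely (5–13%
across algorithms on the reference fixture).

**Limitations.** Homotypic doublets carry no mixed-profile signal — the
sum of two draws from the same profile is a draw from that profile — so
expression-based scorers only see their doubled library size; on a
single-cell-type fixture detection degrades markedly and this is asserted
as expected behaviour, not fixed. Scores are not numerically identical to
any external implementation; the contracts are accuracy on ground truth.

## Ambient-contamination estimation

Counts of cell c in cluster k(c) are modelled as
Mult(t_c, θ_c·η_k + (1−θ_c)·φ_k). The contamination source η_k is fixed
at the pooled observed expression of all *other* clusters (plus a 0.01
Dirichlet smoothing). This pinning is what makes θ identifiable: with a
single shared, freely re-estimated ambient distribution, each cluster
profile can absorb its own contamination and the likelihood is nearly
flat in θ (parameter-recovery experiments gave correlation ≈ 0.3 against
simulated truth even with oracle clusters; the pinned variant gives
≈ 0.99). Contamination is in any case only recognisable through genes a
cell type does not itself express, so the own-type fraction of true
ambient RNA is invisible to any estimator.

With η fixed, θ (initialised at 0.1) and φ (initialised at cluster means)
are estimated by EM; this is a standard EM, so the observed-data
log-likelihood is non-decreasing, which the test suite asserts per
iteration. Convergence is declared when mean |Δθ| < 1e-3 (interpretable
on the contamination scale, unlike a likelihood tolerance); non-convergence
returns results with `converged=False` and a warning. The posterior
ambient share of each observed count splits the matrix into native and
ambient portions that sum to the observation exactly; the decontaminated
matrix is real-valued (stored as the `decontX_counts` assay; rounding is
left to the consumer).

Clusters default to k-means on 30 normalised PCs with k chosen by
silhouette over 2–10; user labels always override, and a single user
cluster is rejected as unidentifiable. A 2-D UMAP (`decontX_UMAP`,
seeded) is stored for report plots.

## Synthetic data generator

The generator emulates a droplet run at the molecule level: cell-type
profiles are Dirichlet(0.1) draws (sparse, well-separated types); the
ambient profile is the uniform mixture of type profiles; empty droplets
draw Mult(t, ambient) with log-normal totals (median ≈ 20); singlets draw
Mult(t, (1−θ)·type + θ·ambient) with log-normal totals (median ≈ 2,000)
and θ ~ Beta(2, 18) (mean 10%); doublets sum two singlet draws of
different types. Defaults: 500 genes, 3 types × 300 cells, 20,000
empties, 8% doublets. A mis-specified variant draws the ambient profile
from an independent Dirichlet for robustness checks.

Because contamination is generated by exactly the mixture mechanism the
estimator assumes, parameter recovery on these fixtures is a fairness
check of the estimator, not evidence about mis-specified real data; the
mis-specified variant and the homotypic fixture probe the obvious failure
axes. The generator does not emulate gene-length/GC bias, overdispersion
beyond the multinomial, batch effects, or spliced/unspliced structure —
so passing tests demonstrate algorithmic correctness under the stated
model, not end-to-end performance on any particular tissue.

Contamination-recovery fixtures are doublet-free: a doublet genuinely is
a mixed droplet and is assigned θ ≈ 0.5 by the model (correctly, from the
model's viewpoint), which would conflate doublet handling with
contamination recovery in one measurement.

## Problem sizes and numerical choices

The shipped test-suite and acceptance fixtures use 150–500 genes and
roughly 1,000–21,000 barcodes — large enough for stable statistics
(binomial/AUROC standard errors well inside the asserted margins) while
keeping a full run to a few minutes on one CPU. Monte-Carlo p-values use
10,000 iterations, matching their enumeration-oracle tolerance of three
standard errors. Tie-breaking and degeneracy rules: tied totals share
average ranks; equal simulated and observed likelihoods count into the
p-value tail (≤ with 1e-9 slack); all-zero cells produce zero metrics
rather than NaN; constant score vectors fall back to quantile thresholds;
MAD = 0 flags no outliers.

## Export formats

Flat files: each assay as MatrixMarket MEX (1-based, integer field when
exact) with barcode/feature sidecars, annotations and embeddings as TSV,
provenance as YAML, all optionally gzipped with a fixed mtime so equal
content gives equal bytes, plus a JSON manifest with SHA-256 checksums.
The manifest documents the mapping onto R single-cell object slots
(assay / meta.data / reductions) so the flat files double as an
interchange format; no binary R serialisation is written. h5ad: X
(cells × genes), layers, obs/var/obsm, provenance in `uns`; gzip, lzf or
no compression. Both paths round-trip counts, annotations and embeddings
losslessly, which the test suite asserts bit-exactly.
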
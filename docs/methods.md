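# Methods

## Problem and model

GABA_A receptors are pentameric chloride channels assembled from subunits
encoded by 19 human genes (alpha1-6, beta1-3, gamma1-3, delta, epsilon, pi,
theta, rho1-3). In single-cell / single-nucleus RNA-seq of human cortex,
oligodendrocyte progenitor cells (OPCs) are identified by expression of the
canonical marker *PDGFRA*, and the question is which subunit transcripts
dominate in that population, whether their covariation suggests candidate
co-assembled receptor stoichiometries, and how the composition shifts with
age.

Because source datasets mix units (UMI counts, raw reads, FPKM), absolute
levels are not comparable across studies. The analysis therefore works with
the **fractional contribution (FC)** of each subunit gene: its share, in
percent, of the expression of the whole 19-gene panel. Three estimators are
provided:

- **FC1** (per cell): each cell's panel vector is normalised to percentages;
  the dataset statistic is the mean ± SD/SE over *defined* cells — cells with
  any panel expression. FC1 is invariant to per-cell sequencing depth.
- **FC2** (per dataset): panel counts are pooled over cells first, then
  normalised. FC2 weighs cells by depth and is *not* depth-invariant; a
  two-cell example in the test suite documents the asymmetry.
- **FC3** (detection): the percentage of cells in which each panel gene is
  detected (count > 0). Its denominator is *all* gated cells, including
  panel-silent ones — deliberately different from FC1's denominator, which
  excludes them.

Cross-dataset aggregation treats datasets as units: unweighted mean with SE
= SD/sqrt(n_datasets) (NaN at a single dataset). A cell-weighted mean is
available behind a flag. SDs are always the sample (n−1) kind; at one
observation they are reported NaN, never 0.

## Gating and counting conventions

"Expressing" means count strictly greater than zero everywhere: marker
gating keeps cells with one or more marker counts (a `min_value` threshold
is exposed for sensitivity analyses), and detection statistics use the same
rule. Cells are gated per dataset, never pooled before gating. Gating is a
pure row filter; values are never modified.

## Quality control and normalisation

QC follows the standard droplet recipe on count units only: keep cells with
`min_features <= detected genes < max_features` (defaults 200 and 3,000)
and mitochondrial percentage below `max_mito_pct` (default 5%), then keep
genes detected in at least `min_cells_per_gene` (default 3) remaining
cells. The filter order — cells first, then genes — is fixed, and the
operation is idempotent. The mitochondrial fraction is taken from cell
metadata when supplied, otherwise computed over genes whose symbol starts
with "MT-". The feature thresholds follow the parameterisation convention
(200 ≤ features < 3,000) rather than prose restatements of it, which
commonly disagree in published methods sections.

`log_normalize` applies `ln(1 + scale_factor * x / total)` per cell
(natural log, scale factor default 10,000 — the de-facto standard), tags
the matrix `LOGNORM`, and QC refuses to run on such data. Zero-total cells
are a contract violation and the error names them.

Symbol harmonisation maps aliases onto canonical symbols, sums columns that
collapse onto one symbol (conserving per-cell totals), and zero-pads absent
panel genes so every panel statistic is well defined; padding is logged.

## Stoichiometry inference

Candidate co-assembly is read from the pairwise Pearson correlation of
subunit FC values. The default observation unit is dataset means (the
per-cell mode is available and every output carries `n_obs`); fewer than 3
observations are refused rather than emitting the r = ±1 artifacts that 2
rows force. Two-sided p-values come from t = r·sqrt(n−2)/sqrt(1−r²) with
n−2 df; zero-variance genes yield NaN. No multiple-testing correction is
applied to the 171 subunit pairs; outputs note this.

The correlation structure is summarised by average-linkage (UPGMA)
clustering under the correlation distance d = 1 − r, computed with
scipy.cluster.hierarchy; ties in agglomeration resolve by scipy's
deterministic ordering, so reruns on identical input are identical.

Segregation analysis asks whether cell types carry distinct panel
signatures. Rows (dataset × cell-type FC vectors) are robustly standardised
per gene — (x − median)/(1.4826·MAD), the normal-consistency constant;
MAD-zero columns are zeroed and flagged — then clustered two-way with
Euclidean distance and average linkage. Euclidean-on-standardised-values is
the natural companion to robust standardisation and pairs with the same
average linkage used for the correlation dendrogram. The row tree cut at
k = 2 is scored against annotated cell types with the adjusted Rand index
(scikit-learn); a single annotated type gives ARI = NaN with the clustering
still returned.

## Co-expression response screen

The response is the raw per-cell sum of the 19 panel genes (no
renormalisation). Every other gene is correlated against it; p-values use
the same t transform. With tens of thousands of cells, p underflows double
precision (the smallest subnormal is ~4.9e-324) for strong correlates and
is stored as 0; ranking is by (p ascending, |r| descending, symbol
ascending), keeping the top-K list deterministic through the underflow
regime. The selection cutoff defaults to p < 4.2e-322, which sits just
above that underflow edge, with k = 1,000. Panel genes trivially correlate
with their own sum and are excluded from the ranking by default (a flag
keeps them); constant genes are excluded with reason "constant". Cells are
pooled across datasets by default (a per-dataset screen is a loop over the
same function). No multiple-testing correction is applied — selection is a
raw p cutoff — and the export manifest records the number of tests.

## Group comparison

Per subunit gene, per-cell FC1 values are compared across age groups
(fetal, pediatric, adolescent, adult). Pairwise comparisons use the
two-sided Wilcoxon rank-sum test: exact enumeration over all
C(n1+n2, n1) rank assignments (midranks, so ties are handled and two
identical tied groups give p = 1) when both groups have ≤ 10 observations;
the tie-corrected normal approximation otherwise. The omnibus test is
Kruskal-Wallis (chi-square approximation, tie-corrected). Each result row
records which path was taken. Significance is flagged at raw alpha = 0.05
with no correction across the 19 subunits; the result carries the test
count. The exact path is authored in-package because the standard exact
implementation does not support ties.

## Synthetic data generator

The generator emulates the structure the analysis assumes, per cell:
type assignment (marker-positive type with probability
`marker_positive_rate`, default 0.12, else uniformly another type);
library factor L ~ LogNormal(0, 0.3); panel total ~ Poisson(
`mean_panel_counts`·L), default 200; panel counts multinomial over
dataset-level proportions drawn once per (dataset, type) as
Dirichlet(kappa·p) around the type's base composition (kappa default 50,
None disables jitter); independent Bernoulli dropout per panel entry
(default 0.1); a deterministic positive marker count (1 + Poisson(1)) for
the cell's own type, so the marker-positive fraction is exactly the type
rate; planted correlates round(panel sum + N(0, noise_sd)) floored at 0;
and background genes Poisson(lambda_g·L) with per-gene rates
~ Exponential(0.1). Counts are integers (UMI-like); an FPKM mode multiplies
by per-gene length factors. Each dataset's stream is seeded from
(master seed, dataset index), so adding datasets never perturbs earlier
ones and a fixed seed is bit-reproducible.

The model-implied detection probability per panel gene,
(1 − dropout)·(1 − E_L[exp(−mean·p·L)]), is computed by numerical
integration over the lognormal library density and used to check FC3
against exact binomial bounds.

What the generator does **not** emulate: transcriptome-wide gene-gene
correlation beyond the planted structure, batch effects, doublets,
ambient RNA, or realistic gene-length and GC biases. Passing tests
therefore demonstrate correctness of the estimators and recovery under the
stated generative model, not robustness to every artifact of real data.

## Numerical choices and degenerate inputs

- Compositions are validated to sum to 1 within 1e-12; FC profiles to 100
  within 1e-9.
- r is clipped to [−1, 1] against floating-point overshoot; |r| = 1 maps to
  p = 0.
- Zero panel total: FC1 profile undefined (excluded, both counts reported);
  FC2 all-NaN only when the whole dataset is panel-silent; FC3 well defined
  regardless.
- Exact rank-sum deviations are compared with a 1e-9 slack so midrank
  arithmetic does not flip boundary outcomes.
- Pipeline outputs are files (MTX triplets, TSV, JSON) rather than
  in-memory handoffs, so stages rerun in isolation; the manifest hashes the
  canonical YAML config and is written even on failure.

## Problem sizes

Tests and the acceptance script run at sizes chosen to give tight
statistical bounds while staying desk-scale: 1,000 cells for conservation,
50×200 fixtures for oracle equivalence, 5,000 cells (FC2) and 20,000 cells
(FC3) for parameter recovery, 8 datasets × 400 cells for segregation,
100 replicate screens of 2,000 background genes × 150 cells, and 300 cells
per age group for comparison power.

## Known limitations

- Dense in-memory matrices: adequate for the synthetic and desk-scale
  processed data this package targets, not for atlas-scale inputs.
- The printed-figure reproduction of the original public datasets requires
  downloading the deposited accessions and is not part of the test suite;
  the registry/ingest layer provides the machinery.
- Correlation-based stoichiometry is evidence of transcript covariation
  only; it cannot establish physical co-assembly of subunits.
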
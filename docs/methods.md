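# Methods notes

This note records the models, conventions and numerical choices behind
`scpcov`, in the order the pipeline applies them.

## Generative model of the synthetic data

The generator produces the latent log2 intensity of peptide *j* (protein
*i*) in cell *c* as

    L_ijc = b_i + o_j + log2(s_c) + log2(e) + phase_ic + diff_ic + type_ic + ε,

with protein baseline `b_i ~ N(base_mean, base_sd)`, peptide offset
`o_j ~ N(0, pep_offset_sd)` (missed-cleavage variant peptides sit
`log2(missed_cleavage_ratio)` below their parent), size factor
`s_c = (d_c / d_ref)³ · κ_c · 2^η` from the cell diameter
`d_c ~ logN(μ_type, σ_type)` (μm), the cluster-B concentration deficit
`κ = 0.8`, per-cell delivery/concentration noise `η ~ N(0, 0.35)`, the
global delivery efficiency `e = 0.95`, and measurement noise
`ε ~ N(0, 0.3)` (log2 units throughout).

Biological effects:

- **CDC periodicity.** 20 proteins per phase carry
  `A·(1[phase(c)=p] − 1/3)` with peak − trough = `A` (default 1.0 log2).
  Phases are discrete labels drawn from fractions 0.50/0.25/0.25
  (G1/S/G2); a continuous cell-cycle angle is deliberately out of scope —
  a discrete label keeps the ground truth checkable against the
  three-phase marker framework.
- **Melanoma subpopulations.** Cluster B (20 % of melanoma cells)
  carries 75 differential proteins with per-protein |log2 FC| drawn
  `U(fc, 2·fc)`, `fc = 1` — "2-fold or more", since planting every
  effect exactly at the downstream 2-fold decision boundary would turn
  that rule into a coin flip on sampling noise. Half the proteins are up
  in A, half up in B. B cells are G1-enriched (0.78/0.18/0.04) and have
  a 0.8× protein concentration per unit volume. With `gradient=True`
  (default), A cells carry a latent position `g ~ U(0,1)` scaling their
  differential effects by `0.3·g` toward the B state, which couples the
  A-up and B-up protein blocks with opposite signs inside cluster A.
- **Cell-type divergence.** 200 unplanted proteins get a constant
  melanoma-vs-monocyte offset `~ N(0, 0.5)`. These offsets are constant
  within a type, so all within-type statistics (markers, differential
  tests, gradients) are unaffected; they exist so that the first
  principal component genuinely separates the cell types, as it does in
  real data, rather than through missing-data artifacts.

**Missingness** is applied per measurement:
`P(detect) = logistic(a + b·L)` with `a = −6`, `b = 0.5`, plus a 5 %
missing-completely-at-random component. The free intensity-scale
parameters (`base_mean = 11`, `base_sd = 4.5`, `pep_offset_sd = 2`) were
calibrated once, by integrating this logistic over the simulated
intensity distribution, so that the default configuration yields ≈ 60 %
protein-level completeness and a ≈ 20-fold negative-control deficit;
they were then frozen. Negative-control droplets draw background
intensities centered so their expected linear-scale total is
1/`background_ratio` (= 1/20) of the mean single-cell total (with the
lognormal mean-correction term so the expectation is exact). Carrier
(100-cell) and reference (5-cell) channels are bulk-pool expectations
per isobaric set, with no single-cell delivery loss.

**Planted structure lives in the upper half of baseline abundance.**
Marker and differential lists in real experiments are by construction
restricted to quantifiable proteins (observation floors of 150 cells or
50 % of cells); planting effects on proteins the instrument essentially
never detects would make "recovery versus truth" meaningless.

**Batches.** Batch 1 is 14-cell isobaric sets with carrier + reference;
batch 2 (30 % of melanoma cells) is 3-cell sets without carrier,
covering only ~35 % of proteins (always including the differential
ones, mirroring targeted coverage of the relevant proteome), with
per-protein additive shifts `N(0, 0.3)` and multiplicative scale
`exp(N(0, 0.1))` on the deviations.

What the generator does **not** emulate: spectrum-level structure (m/z,
retention time, co-isolation), correlated peptide-level missingness
within an isobaric set, label chemistry, protein complexes beyond the
planted blocks, and heavy-tailed measurement noise. Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to every artifact of real instruments.

## Normalization and filtering

The normalization follows the SCoPE2 convention: (1) divide each
single-cell intensity by its set's reference-channel intensity for that
peptide (skipped when no reference exists, as in 3-plex non-isobaric
data); (2) divide each cell column by its median; (3) divide each
peptide row by its mean over observed cells; (4) log2; (5) collapse to
proteins by the median peptide; (6) re-center columns (median) and rows
(mean). Step (6) alternates row and column centering until the matrix
stops changing (tolerance 1e-12): on skewed data a global constant
trades between the row means and column medians, so both cannot be
exactly zero; the procedure ends on the column step, making observed
column medians exactly zero, and is idempotent. Cells with fewer than 2
observed peptides are dropped with a warning.

The CV filter first divides each cell by its median intensity (making
the filter exactly invariant to rescaling any cell), then expresses each
peptide relative to its mean over cells; for every protein with ≥ 6
observed peptides in a cell the CV is the sample sd over mean of those
relative levels, and the per-cell summary is the **median** protein CV
(the mean is available via `summary="mean"`; which summary the original
filter used is not documented anywhere authoritative, and the median is
the robust convention). Threshold 0.41. Negative controls fail this
filter because their background draws are mutually inconsistent across
peptides of a protein.

Delivery efficiency is summarized by the geometric mean of the
single-cell/reference ratio distribution (×5): the arithmetic mean of a
right-skewed lognormal ratio distribution is biased upward and does not
estimate the configured efficiency; the arithmetic mean is reported
alongside. The missed-cleavage metric pairs each missed-cleaved peptide
with its fully cleaved counterpart within the same cell and sums the
two intensity groups before taking the ratio. The size-intensity
correlation compares the cell diameter with the per-cell **median**
observed reporter-ion intensity: over a dynamic range of several orders
of magnitude the linear-scale mean is dominated by the few brightest
peptides and becomes an unstable location estimate, whereas the median
tracks the cell's overall signal level robustly.

## Imputation and embeddings

`CellSimilarityImputer` fills a missing (protein, cell) entry with the
unweighted mean of the protein's observed values among the k = 3 most
similar cells, similarity being Pearson correlation on pairwise-observed
proteins (Euclidean distance available behind a flag). Ties in
similarity resolve by stable sort order; entries with no observing
neighbor fall back to the protein mean and are counted.

Weighted PCA weights protein *i* by `w_i = Σ_j r²_ij` (self term
included, so an uncorrelated protein gets weight 1; a zero-variance
protein has its off-diagonal correlations defined as 0) and multiplies
the centered protein values by `w_i` before the SVD. Correlation PCA
takes the top eigenvectors of the pairwise-complete cell × cell Pearson
matrix; pairs sharing < 3 observed proteins get correlation 0 (counted)
rather than NA, keeping the matrix complete for the
eigendecomposition. Component signs are fixed by making the
largest-magnitude loading (or score) positive. The two-cluster split is
seeded 2-means (50 restarts) on the first two components, run on
canonically sorted rows so the partition is invariant to cell order;
label A is the larger cluster, ties broken toward higher mean PC1.

## Cell-cycle machinery

Bulk phase ANOVA normalizes precursors to the sample median and each
precursor to its mean across samples, log2-transforms, pools both cell
types, and compares phases per protein group by one-way ANOVA with BH
q-values. Candidates for markers must be bulk-significant (q < 0.01),
rank in the top 10 of their peak phase by fold change, and have ≥ 2
peptides with positive median pairwise correlation in the single-cell
data.

Marker construction enumerates all 2- and 3-subsets per phase, averages
observed member levels per cell, and selects per phase — sequentially in
G1, S, G2 order — the two disjoint subsets maximizing mutual Pearson
correlation subject to all correlations against previously selected
phases' subsets being negative. If no pair is feasible the objective
relaxes to (within-phase − worst cross-phase correlation) and the phase
is flagged in the provenance, which also records every candidate pair's
scores. The phase marker is the union of the two winning subsets; the
per-cell marker value is the mean of its observed members.
Cross-validation correlates the 6 × 6 marker-group correlation matrices
of training and held-out cells over the 15 off-diagonal upper-triangle
entries only — the diagonal is identically 1 and would inflate the
agreement.

The protein screen uses Spearman correlation on pairwise-observed
values with BH across all protein × phase tests; the default reporting
threshold is FDR < 5 % with 1 % available in configuration (both
conventions appear in the field). Set-level ANOVA compares the six
distributions of member correlations (two types × three phases) on raw
correlation values; a Fisher z-transform is available behind a flag but
off by default. The between-type similarity score is the Pearson
correlation of the two types' 3-phase median profiles. Split-half
reproducibility filters proteins on the full matrices (so both halves
test the same features), splits cells per type with a seeded generator,
and correlates the two halves' median vectors.

Greedy phase assignment builds the 3N vector of per-cell mean observed
marker abundances, sorts by value descending with ties broken by cell
id ascending then phase order G1 < S < G2 (full determinism and
permutation stability), and fills bins of capacity floor(N·q) for S and
G2 with the remainder to G1. Cells missing an observed marker for any
phase are assigned NA up front rather than competing with partial
information, which would bias the quotas.

## Subpopulation analysis

All statistics use observed values only. PSEA pools member-protein
levels and applies Welch's t-test between clusters; "effect size > 50 %"
is interpreted as |difference of cluster means on log2 scale| ≥
log2(1.5). Differential testing is per-protein Kruskal–Wallis (the
two-group case equals the Wilcoxon rank-sum chi-squared form) with the
2-fold rule applied to the difference of cluster **medians** of log2
relative levels (means available in configuration). The concentration
comparison uses a two-sided Mann–Whitney test (robust, no distributional
commitment) on total signal over sphere volume (π/6)d³, plus a
common-slope regression of log2 signal on log2 volume with
cluster-specific intercepts. Heatmap ordering is fixed (average linkage
on correlation distance, optional annotation grouping first) for
reproducibility. The gradient embedding is correlation PCA restricted to
the differential proteins, with per-cell means of the A-up and B-up
markers and their Spearman association with PC1.

## Integration

Each dataset is re-centered within its own cells, the protein
intersection is taken, and batch correction equalizes per-protein batch
means and pools variances on observed values (missing entries stay
missing). The scale target is the pooled *within-batch* standard
deviation — using the combined sd would leak the between-batch spread
into the scale and break idempotence. A batch with zero variance or a
single observation for a protein gets a location-only adjustment
(counted). This deterministic location/scale equalization is the
implementation; empirical-Bayes shrinkage of the batch parameters is a
refinement that changes none of the testable contract (batch means
equal to < 1e-8) and is not included. Covariates are not used.

## Problem sizes and evaluation fixtures

The default evaluation experiment is 600 + 600 single cells, 60
negative controls and 1200 proteins in two batches — the full pipeline
runs in about a minute. False-discovery calibration aggregates 20
replicate simulations of 300 cells × 400 proteins; tested features are
global-null by construction (unplanted proteins against markers built
from the planted periodic ones; permuted cluster labels for enrichment).
The differential-recovery fixture is 600 melanoma cells (≈ 480/120
A/B), 75 planted ≥ 2-fold proteins, gradient off — that fixture
measures the clean cluster-effect recovery, while the default fixture
keeps the gradient on. Unit tests use 150–300 cells and 200–300
proteins with the same defaults otherwise.

## Known limitations

- Pairwise-complete correlation matrices are not guaranteed positive
  semi-definite; the embedding uses the top eigenvectors, which is safe,
  but small negative eigenvalues are clipped in variance fractions.
- The marker search is sequential across phases (G1 → S → G2); a joint
  search over all three phases is combinatorial and was not needed — on
  data with genuine phase structure the sequential and exhaustive
  solutions coincide (tested).
- The greedy quota assignment forces global phase fractions; if the true
  composition deviates from the quotas the error rate rises
  accordingly.
- MNAR strength in real data is not identifiable from the summaries the
  generator is calibrated to; the defaults reproduce completeness and
  background levels, not the full detection curve.
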
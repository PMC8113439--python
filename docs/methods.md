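# Methods

## Scope and data model

The package operates on a region × gene matrix of normalized expression
(`ExpressionAtlas`), a phenotype map assigning one value per region
(`PhenotypeMap`), region centroid coordinates or a Euclidean distance matrix
in mm, and a table of gene categories (`CategoryTable`).  Atlas
preprocessing (probe selection, normalization, sample-to-region assignment)
is upstream of this package: inputs are assumed pre-summarized.  All
alignment is by region/gene identifier, never by row position.

## Category construction

GO structure is read from OBO 1.2 (via `obonet`); only `is_a` edges define
the hierarchy, with `part_of` traversal available behind a flag but off by
default.  Obsolete terms are retained (flagged) and never traversed.
Annotations are read from GAF 2.x with NOT-qualified and ND-evidence rows
excluded, then propagated to all transitive `is_a` ancestors and
deduplicated.  Gene identifiers may pass through a static two-column mapping
table (unmapped genes dropped and counted); no network lookups are
performed.  Category gene sets are intersected with the measured-gene
universe **before** the size filter (defaults 10 ≤ s ≤ 200,
`biological_process` namespace), so the recorded size s always matches the
pool from which the random-gene null resamples.

## Scoring and aggregation

Gene scores are Pearson correlations between each gene's expression profile
and the phenotype over pairwise-complete regions (Spearman optional, average
ranks for ties; genes with fewer than 3 usable regions or constant profiles
are dropped).  Pearson is the default because spatial gene–phenotype
association is most commonly quantified that way; both choices are recorded
in the run configuration.  Category scores are the arithmetic mean of member
gene scores, on the signed scores by default with a right-tailed test; an
absolute-value transform is available.  The signed/right-tailed default is a
design choice — the directional convention differs across published
pipelines — and the configuration tag is stored with every null bank so that
a bank can never be reused under a different scoring configuration.

## Null models and p-values

**Random-gene null.**  For each category size s, the null is the
distribution of the mean of s scores drawn uniformly *without replacement*
from the scored-gene pool.  The default is 40,000 Monte-Carlo resamples
summarized by a fitted Gaussian (mean, ddof-1 SD).  Resampling uses a
shared-key construction: each pool element receives an i.i.d. uniform key
and the s smallest keys form a uniform s-subset for every s simultaneously,
so one pass serves all category sizes at O(n_samples × N) cost.  Passing
`n_samples=None` replaces the Monte-Carlo fit by the exact finite-population
moments — mean m of the pool and variance (v/s)·(N−s)/(N−1) — which are the
infinite-resample limit of the fitted Gaussian.  The two modes agree within
Monte-Carlo error (tested); the analytic mode is the default inside CFPR
audits, where rebuilding a 40,000-resample null for every phenotype in a
multi-thousand-phenotype ensemble would dominate the cost without changing
the answer.

**Ensemble null.**  For each category, the same scoring pipeline is run
against a bank of surrogate phenotypes, giving n_null null category scores
summarized per category by a fitted Gaussian.  The bank depends only on the
atlas, categories and ensemble — never on the phenotype under test — so it
is a one-off computation cached and reused across phenotypes (verified by
call-count accounting in the tests).  Defaults: 40,000 maps for p-value
estimation, 10,000 for CFPR audits, both configurable.

**p-values.**  The default `p_Z` is the Gaussian tail
`1 − Φ((score − μ̂)/σ̂)` (two-sided doubles the smaller tail; floored at the
smallest positive double).  The Gaussian fit slightly underestimates far-tail
p-values relative to a full permutation test; an empirical permutation mode
(`p_mode="empirical"`, resolution 1/(n+1)) is available wherever the null
samples are retained.  Multiple testing uses Benjamini–Hochberg step-up
q-values (`q_FDR`); BH was chosen over Storey's pFDR for determinism and
conservatism, and the full result table is always returned, never only the
significant rows.

## Surrogate phenotype ensembles

*SBP-random* maps are i.i.d. standard normal per region.  *SBP-spatial*
maps come from the spatial-lag model `u = (I − ρW)⁻¹ε` with
`W_ij = exp(−d_ij/d₀)` for i ≠ j, zero diagonal, rows normalized to unit
sum.  Row normalization bounds the spectral radius of W by one, so
`I − ρW` is invertible for every ρ < 1; this normalization is an
implementation choice recorded in the ensemble spec.  Defaults ρ = 0.8;
d₀ is estimated from the data by fitting `CGE(d) = A·exp(−d/λ) + B` to
all-gene correlated gene expression versus distance and taking d₀ := λ.
All maps are standardized per column (enrichment uses correlations, which
are scale-free); note that per-map standardization removes each map's
common mode, so the realized correlation structure is the SAR covariance
minus its common component.  Ensembles are regenerable bit-identically from
their JSON spec (kind, parameters, seed); one master seed drives all draws.

## Category diagnostics

⟨r⟩ is the mean of the s(s−1)/2 upper-triangular entries of the category's
gene × gene Spearman correlation matrix (pairwise-complete regions; defined
for s ≥ 2).  `R²_exp` is `1 − SS_res/SS_tot` of the three-parameter
exponential fit to the category's CGE(d) (Pearson across the category's
genes per region pair; s ≥ 3).  The fit is nonlinear least squares
initialized at A₀ = max(y) − min(y), λ₀ = median(d), B₀ = min(y) with λ
constrained positive; non-convergence returns the best iterate flagged.  A
model-free alternative, −ρ_Spearman(CGE, d), is always reported alongside.
The cortex/non-cortex style two-class diagnostic is a per-gene two-sided
Wilcoxon rank-sum test (exact for small groups) with BH correction.

## CFPR auditing

CFPR(category) = 100 × (#phenotypes with q_FDR < α) / n_phenotypes, default
α = 0.05.  Three conditions: *reference* (each gene's profile independently
permuted across regions, preserving missingness — destroys coexpression and
sets the statistical floor), *sbp_random*, and *sbp_spatial*.  The inner
GCEA defaults to the random-gene null because CFPR measures the
conventional method's bias; supplying an ensemble null bank instead audits
the corrected method, which should sit at the nominal rate.  Audits stream
phenotypes in chunks and keep only significance counts (optionally the full
rejection matrix).  Mean CFPRs average over all categories including those
with CFPR = 0.  Summaries: fold-changes of mean CFPR between conditions,
equiprobable CFPR bins (default 8, sizes differing by at most one) with
per-bin ⟨r⟩, R²_exp and literature-report proportions, and per-category
CFPR change between the spatial and random ensembles.

Under a calibrated null with m categories, the expected mean CFPR is taken
as 100·α/m (BH under the global null rejects with probability ≈ α,
typically one category); tests compare audited rates to this nominal value
within 3 Monte-Carlo SE estimated from the per-phenotype rejection counts.

## Synthetic fixtures

`make_synthetic_atlas` draws region centroids uniformly in a cube (default
edge 10 mm, 100 regions × 2,000 genes — seconds-scale tests).  Each
category owns a latent map; a member gene is
`w·L_c + √(1 − w²)·ε + γ·G`, all genes standardized, so the population
within-category correlation is w² (an analytic target used by the tests).
Filler genes are noise plus the shared gradient term.  `G` is a linear
gradient along a random direction — a deterministic stand-in for the
dominant low-dimensional expression gradients of real atlases.  For
spatially structured categories (ℓ set) both the latent *and* each gene's
idiosyncratic component are drawn from a Gaussian process with correlation
`exp(−d/ℓ)`: a shared latent alone is constant across member genes and
would cancel out of the across-gene CGE correlation, and the exact
exponential covariance makes ℓ the true correlation length (the spatial-lag
generator's realized decay length is a kernel- and geometry-dependent
multiple of its d₀, which would leave no analytic recovery target).
`make_gradient_aligned_phenotype` returns the leading spatial principal
component of the expression matrix, sign-fixed to correlate positively with
its top-loading gene.

What the fixtures do *not* emulate: donor structure, probe-level noise,
hemispheric or areal sampling bias, realistic GO overlap topology (random
audit categories are uniform gene subsets), or missingness mechanisms
beyond uniform patterns.  Passing tests demonstrate the statistical
mechanisms — coexpression-driven variance inflation, spatial-autocorrelation
matching, gradient offset — not agreement with any particular real atlas.

## Problem sizes and numerical choices

The calibration script runs the reference condition at the full matrix
shape (213 regions × 19,417 genes) with 2,000 categories and 2,000 random
phenotypes using the analytic random-gene null; the test suite uses
1,000 × 1,000 and smaller fixtures.  At these ensemble sizes the mean
reference CFPR is resolved to well within an order of magnitude.
Correlations clip to [−1, 1]; degenerate cases error early (constant
phenotype, s < 2 for ⟨r⟩, s < 3 for CGE, fewer than 4 distinct distances
for the exponential fit); a spatial-scale fit with R² < 0.1 is flagged
weak rather than trusted.  The exponential-fit λ estimated from CGE of
standardized genes carries a modest (~10–20%) downward bias because
per-gene centering double-centers the latent covariance; this is a property
of the estimator on any standardized data, visible in the parameter-recovery
tests and within their 25% tolerance.

## Known limitations

* Gaussian-fit p-values are anti-conservative in the far tail; use the
  empirical mode for citable p-values on a specific analysis.
* Spearman scoring with missing expression falls back to a per-gene loop
  and is slow on large ensembles.
* The spatial-lag W normalization follows one published convention;
  surrogate families that match variograms or spin maps are out of scope.
* Hierarchical/conditional GO testing and GSEA-style rank statistics are
  not implemented.
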
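# Methods

This note documents the statistical procedures implemented in cortexlink,
the choices made where the methodology is genuinely open, the design of the
synthetic cohort generator, and the limits of what the test suite
demonstrates.

## Step 1: cortical-thickness phenotype maps

Regional CT values (mm, 68 cortical areas) are residualized on an
intercept, age (years), sex (0/1) and total intracranial volume (mm³) by
ordinary least squares, fitted on the pooled sample entering each specific
comparison: patients + controls pooled for the case–control contrast, and
both timepoints pooled (each subject contributing two records) for the
paired contrast. Pooling keeps the group/timepoint contrast visible in the
residuals; per-group residualization would absorb it. `residualize_ct` also
accepts Welch instead of pooled-variance *t* for the independent contrast
(`equal_var=False`); the pooled-variance Student *t* is the default.

Sign conventions: case–control *t* is patients − controls; longitudinal *t*
is 8W − 0W, so cortical thinning is negative. Downstream PLS sign-aligns
its component to the map, so these conventions do not affect gene lists.

FDR across the 68 (or 34) regions is Benjamini–Hochberg. Degenerate paired
contrasts (zero within-pair variance with a nonzero shift) report ±inf with
p = 0 and a warning rather than raising — this arises only in noise-free
synthetic data.

Reduction rates divide by (baseline − scale minimum); a baseline at the
scale floor (e.g. PANSS-P = 7) makes the rate undefined and yields NaN with
a warning. Rates are ≤ 1 by construction and negative when symptoms worsen.

## Step 2a: expression preprocessing

The five-step reduction from probe-level data to a 34-region × gene matrix
names each concrete choice, all configurable:

* **Intensity filter**: a probe survives when its above-background fraction
  over all samples is strictly greater than 0.5.
* **Representative probe**: per gene, maximal *differential stability* —
  the mean over donor pairs of the Pearson correlation between the donors'
  region-mean profiles (computed over regions both donors cover). Ties go
  to the lexicographically smaller probe id; a single-donor dataset falls
  back to highest mean expression.
* **Aggregation**: left-hemisphere samples only; a region's value is the
  mean over a donor's samples in it. A region covered by no donor is an
  error (the pipeline requires a complete 34-region response).
* **Normalization**: per donor and gene, a scaled robust sigmoid across
  regions, x′ = 1 / (1 + exp(−(x − median)/(IQR/1.35))), min–max rescaled
  to [0, 1]; donors are then averaged (genes present in all donors only).
  A zero IQR (flat profile) maps to 0.5 everywhere with a warning.

The robust sigmoid is monotone, so per-donor regional rankings are
preserved; the subsequent PLS z-scores each gene column, so the [0, 1]
codomain is a convenience, not an assumption.

## Step 2b: spatial PLS

With a univariate response the first PLS component has the closed form
w ∝ X_cᵀ y_c (unit ℓ2 norm), where X_c is the column-centered,
column-standardized region × gene matrix and y_c the centered *t* map; the
implementation uses this form directly (the test suite cross-checks it
against an independent NIPALS implementation). Standardizing gene columns
makes weights comparable across genes of different dynamic range.

* **Permutation test** (default 1,000): the map is randomly permuted across
  regions (no spatial-autocorrelation-preserving null), the component is
  refitted, and p = (1 + #{r_null ≥ r_obs}) / (n_perm + 1).
* **Bootstrap Z** (default 500): regions — the observational unit of the
  regression — are resampled with replacement; each refitted weight vector
  is sign-aligned to the original by dot product; Z = weight / bootstrap SD,
  two-sided p from N(0,1), BH-FDR across genes. A bootstrap draw with a
  constant response is redrawn (at most 10 attempts).
* **Gene lists**: positive (Z > z_thresh) and negative (Z < −z_thresh)
  sets, both additionally requiring q < α (defaults z_thresh = 3,
  α = 0.05). The two conditions are applied jointly.

The component's *r* (spatial correlation of scores with the map) and
*r²* (variance explained) are reported as separate quantities; they are
not interchangeable and the summary prints both.

Enrichment is a deliberately plain hypergeometric over-representation test
of a query list against caller-supplied GMT sets, intersected with an
explicit background (default: all genes surviving preprocessing), upper
tail, BH-FDR across sets. No term clustering, database merging or
identifier mapping is attempted; results therefore depend entirely on the
GMT files the caller provides.

## Step 3: methylation–symptom CCA

Gene-level methylation is the unweighted mean beta over the gene's CpGs
(a CpG annotated to several genes contributes to each); longitudinal change
is baseline minus follow-up (Δ = β₀ᵂ − β₈ᵂ), so demethylation after
treatment is positive.

**Laplacian score.** The subject-similarity graph is k-NN (default k = 5)
on Euclidean distances over all features, symmetrized (an edge exists when
either endpoint is in the other's k nearest), heat-kernel weights
S_ij = exp(−d²_ij/σ) with σ = the mean squared distance to the k nearest
neighbours, no self-loops. With D the degree matrix and L = D − S, feature
r scores L_r = x̃ᵀLx̃ / x̃ᵀDx̃ where x̃ is the feature centered by its
degree-weighted mean. Smaller is better (the feature varies smoothly over
the graph); the s = 30 (default) lowest-scoring features are kept, ties
broken by gene symbol. Constant features get a NaN score and the worst
rank. A warning is issued when s approaches n − t, where canonical
correlations are inflated by overfitting.

**CCA.** Both blocks are column z-scored. Weights come from QR
decompositions of the centered blocks and the SVD of Q_xᵀQ_y (the whitened
cross-covariance); singular values are the canonical correlations, and
weights are scaled so variates have unit variance. A rank-deficient block
raises an error advising a smaller s rather than silently regularizing.

**Inference.** Rows of the clinical block are permuted (10,000 by
default); each permutation records its *maximum* canonical correlation, and
P_FWE(mode i) = (1 + #{max_null ≥ ρ_i}) / (n_perm + 1) — max-statistic
family-wise control across modes, so P_FWE is non-decreasing in mode
index. Loadings for a significant mode are Pearson correlations of each
standardized methylation feature with the clinical variate V, two-sided p
from the exact *t* reference, BH-FDR across the s genes. One P_FWE is
reported per mode (not per gene); per-gene inference lives entirely in the
loading table.

`run_step3` runs both analyses — baseline levels vs baseline PANSS
(z-scored subscale totals) and Δ vs reduction rates — with feature
selection performed separately within each analysis on its own X block,
and subjects missing any required assessment dropped pairwise.

## Synthetic cohort generator

The generator emulates the reference study design: 42 patients at baseline
with 4 follow-up dropouts (38 treated scans and paired methylation/PANSS),
38 controls, 68 cortical regions, 6 expression donors sampled only in the
left hemisphere, two timepoints. Gene-panel sizes are desk-scale by
default — 200 genes, 2 probes per gene, 5 CpGs per gene — so the full
pipeline runs in seconds; all counts are configurable. Every operation
draws from a named substream of the master seed (SeedSequence spawn keys),
so a seed fully determines all outputs and stages can be regenerated
independently.

* **CT**: region baseline means ~2.5 ± 0.3 mm; covariate effects linear
  (age −0.005 mm/yr, sex +0.03 mm, TIV 2·10⁻⁷ mm/mm³); measurement noise
  0.05 mm; follow-up = baseline + planted thinning vector (default
  −0.05 ± 0.03 mm per region) + 0.02 mm scan–rescan noise.
* **Expression**: gene j's regional profile is
  base_j + w*_j · z(t-map) + spatial residual + donor offset + sample noise,
  expanded to probes with constant probe offsets plus probe noise. The
  spatial residual (sd 1.0, drawn per gene × region and shared across
  donors and samples) represents each gene's own regional expression
  pattern; it is what keeps per-gene map correlations away from ±1 so that
  recovered weights remain proportional to planted ones — donor averaging
  removes sample noise but not this term. Planted unannotated probes and
  below-background probes (with exact planted counts), right-hemisphere
  and unassigned samples exercise every preprocessing filter.
* **Methylation/clinical plant**: a single latent factor z per subject
  drives both the methylation deltas of a known gene subset (default the
  first 20 genes, loading 0.03 beta units) and the three reduction rates.
  With equal loadings and independent Gaussian residuals, the population
  first canonical correlation between the blocks is c_x·c_y where c_b is
  each block's best-combination correlation with z; block noise is solved
  from c_x = c_y = √ρ so the population value equals the requested ρ
  exactly (ρ = 0 plants full independence; baseline methylation and
  baseline PANSS are always independent). PANSS follow-up scores are
  integers reconstructed from the planted rates, which perturbs the rates
  by at most 0.5/(baseline − minimum) ≈ 0.02 — negligible at the ±0.1
  recovery tolerance.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring regions, batch/chip effects and cell-type composition in
blood methylation, non-Gaussian symptom trajectories, missingness other
than follow-up dropout, and probe intensity distributions (background
status is a planted flag, which is all the filter consumes). Passing tests
therefore demonstrate the statistical machinery — calibration of the
permutation nulls, correctness of the estimators, recovery under the
planted model — not robustness to those real-data complications. In
particular the plain region-permutation null is anti-conservative on maps
with strong spatial autocorrelation; on real data a spin-style null should
be preferred (out of scope here).

## Problem sizes used by the validation suite

Null calibration runs 200 replicate cohorts with 199 permutations each,
per test: the PLS null uses 10-patient cohorts with a 60-gene zero-weight
atlas (2 donors, 1 sample/region); the CCA null uses 40-subject cohorts
with a 10-gene panel, s = 5 selected features and ρ = 0. Rejection counts
are checked against the exact binomial 95% band around α = 0.05. Recovery
runs 50 replicates of the reference 200-gene configuration for PLS weight
recovery (corr > 0.9) and 50 cohorts of n = 200 with planted ρ = 0.8 for
canonical-correlation recovery (|ρ̂₁ − 0.8| < 0.1); the
significant-longitudinal/null-baseline pattern is checked at n = 200 with
999 permutations. The demo uses s = 15 features at n = 38 — with s = 30
features on 38 subjects (the module-level default) the permutation null of
the maximum canonical correlation sits near 0.98 and no realistic planted
effect reaches significance; the choice is reported in the run summary.

## Known limitations

* PLS inference covers the first component only; later components are
  fitted nowhere.
* CCA has no regularized/sparse variant, so s must stay well below n.
* The ORA is only as meaningful as the supplied GMT sets and background.
* Euler-number QC consumes externally computed Euler numbers; surface
  reconstruction and its quality metrics are upstream of this package.
* The bootstrap Z reference is the standard normal; with 34 regions the
  bootstrap SE itself is noisy, and |Z| thresholds should be read as
  rankings more than exact tail probabilities.
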
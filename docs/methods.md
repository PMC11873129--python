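# Methods

`comethnet` implements a desk-scale DNA co-methylation network analysis for
post-mortem brain cohorts: weighted module detection on 450K-style beta
values, module-eigengene association with binary neuropsychiatric traits,
expression-weighted cell-type enrichment (EWCE) of module genes against a
single-nucleus reference, and clumping + thresholding polygenic risk scores
(PRS) refined to the genomic windows around a module's CpG sites, with
time-to-event modelling of depression conversion. A synthetic-data
generator with fully recorded planted truth stands in for the restricted
cohort data and defines the conditions under which the pipeline is
validated.

## Preprocessing

Probes are kept when their median absolute deviation (MAD) across samples
exceeds the median probe MAD — computed within each brain region
separately — and only probes passing in *every* region enter the network,
so the same probe universe underlies all regions. Each probe is then
residualised by ordinary least squares on age, sex, technical batch,
NeuN+ neuronal proportion and post-mortem interval (categoricals
treatment-coded against the first level); the fitted intercept is added
back so values keep the beta scale, though residuals may leave [0, 1].
Residualisation is idempotent and leaves the probes exactly orthogonal to
the regressed covariates. Outlying samples are flagged when any of the
first four principal-component scores exceeds 3 SD — a reproducible
surrogate for visual PC inspection; flags are advisory and the pipeline
drops flagged samples by default.

## Network construction and module detection

The network is unsigned: adjacency `a_ij = |cor(i,j)|^β` with Pearson
correlation on residualised betas. The soft power β is scanned over 1–20;
for each power the connectivity distribution is split into ten
equal-occupancy bins and the scale-free fit is the R² of log10 density
against log10 mean connectivity (density = bin fraction / bin width, which
makes equal-occupancy binning informative). The selected power is the
smallest with R² ≥ 0.8, falling back to the argmax; a user override is
available (`--power`), mirroring the common practice of fixing the power
per region.

Similarity is the topological overlap matrix,
`TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, and 1 − TOM is
clustered by average linkage. The tree cut is a deliberately simple,
reproducible surrogate for dynamic tree cutting:

1. static cut at the 0.99 quantile of merge heights, applied recursively
   to any cluster larger than 3× the minimum module size (default 100);
2. clusters below the minimum size go to `grey`;
3. probes whose absolute correlation with their cluster's eigengene falls
   below 0.3 (`kme_min`) are scattered leaves and also go to `grey` — the
   analogue of the dynamic cut's core-scattering criterion, without which
   weakly variable noise probes are absorbed into module peripheries;
4. modules whose eigengenes correlate above 1 − `merge_cut` (default
   0.15) are merged;
5. labels follow the conventional colour sequence in decreasing size
   order.

For probe sets above `max_block` (default 10 000) the probes are
pre-partitioned by k-means on the top-8 principal-component loadings of
the probe correlation structure, blocks capped at `max_block`; on planted
two-module data the blockwise and single-block paths agree (ARI ≥ 0.9).

Module eigengenes are the first right singular vector of the standardised
module submatrix, scaled to unit variance and sign-oriented so the
eigengene correlates non-negatively with the module's mean standardised
profile; `variance_explained` is the first eigenvalue's share.

## Module–trait association

Binary traits use Spearman correlation (Pearson on midranks — exact
permutation p for n ≤ 9, t-approximation otherwise); continuous traits use
Pearson. Before testing, modules still associated (p < 0.05) with any
confound are excluded; the screening list defaults to the residualised
covariates (exactly orthogonal after regression, so they can never falsely
exclude) plus the Braak Lewy-body and neurofibrillary-tangle stages. The
Bonferroni threshold is 0.05 / number of surviving modules, per region.
Thresholds are printed with two significant figures when the leading
digit is 1 or 2 and one otherwise (the uncertainty-reporting convention),
e.g. 0.05/27 → 0.0019, 0.05/8 → 0.006.

Probe-level follow-up: module membership (MM) is the Pearson correlation
of a probe with its own module eigengene; probe significance (PS) is the
per-probe Spearman p against the trait; their relation is summarised by
Pearson correlation of MM with −log10 PS. Three-group sensitivity
analyses (e.g. no depression / depression / premorbid depression) use
pairwise two-sided Wilcoxon rank-sum tests — exact for groups ≤ 10 without
ties, normal approximation with tie and continuity correction otherwise —
with Benjamini-Hochberg correction over the three pairs, optionally after
residualising the eigengene on disease-stage covariates.

## Gene mapping and ontology enrichment

Probes map to gene symbols via the manifest annotation (multi-gene
entries split on `;`, uppercase-normalised, deduplicated); the background
is every annotated probe entering the network. Ontology enrichment
corrects the array's per-gene probe-count bias by resampling: null sets
are drawn as *probe* sets of the target's probe count and mapped to
genes, so genes covered by more probes are proportionally more likely
under the null. p = (1 + #{null ≥ observed}) / (reps + 1) with BH across
terms. In the unbiased limit (one probe per gene) this converges to the
hypergeometric tail, which the tests verify. Term maps are plain file
inputs; no semantic merging of related terms is attempted.

## Cell-type specificity and EWCE

From single-nucleus counts, genes with zero total expression or without
differential expression across cell types (vectorised one-way F-test on
log1p counts, BH q ≥ 1e-5) are dropped as uninformative; specificity is
each gene's mean expression per type divided by the row sum (rows sum
to 1). The EWCE bootstrap compares the target set's mean specificity per
type with `reps` random same-sized gene sets from the universe;
`sd_from_mean = (obs − mean_null)/sd_null`, p by the add-one rule
(minimum 1/(reps+1), so BH stays stable), BH across the types tested at
the chosen annotation level.

The conditional test matches null sets to the target's specificity
profile in a controlled cell type: genes are binned into ten quantile
bins of controlled-type specificity, each null gene is drawn from its
matched target gene's bin, and in the controlled type itself the null
carries the matched target gene's own specificity. The exact substitution
is deliberate: bin-sampling alone leaves an ~N(0,1) residual in the
controlled type's own score (the target is exchangeable with bin-matched
nulls within bins), whereas exact profile matching nulls the controlled
type by construction, so only enrichment independent of the controlled
type survives in the other types. Empty bins widen to their neighbours
with a warning; with no controlled type the test reduces exactly to the
unconditional bootstrap.

## Polygenic scores and survival

Summary statistics are filtered at INFO ≥ 0.9, strand-ambiguous (A/T,
C/G) variants dropped, and effect alleles aligned to the genotype panel
(sign flips where the panel counts the other allele). Clumping is greedy:
visit variants by ascending p (ties: smaller position, then id); each
index variant removes unclumped neighbours within 1000 kb with dosage
r² > 0.1 — the standard defaults of the reference scorer. Scores are
per-allele averages `Σ dosage·β / (2·n_variants)` (a flag switches to raw
sums) at the usual threshold ladder 1, 0.5, 0.05, 0.005, 5e-4 … 5e-8,
with per-variant mean imputation of missing dosages. The refined score
restricts variants to merged ±1 Mb windows around the module's CpG
coordinates (the conventional span of local *cis* methylation
quantitative trait loci).

Binary association uses a linear model of depression status (any visit
with Geriatric Depression Scale, GDS ≥ 5) on sex + the top three genetic
principal components (from the centred dosage SVD, no LD pruning at desk
scale) plus the PRS; incremental R² is the R² gain over the
covariate-only model, with Wald p and BH-FDR jointly across the full
2 × 9 score-set × threshold family (18 tests).

Conversion to depression requires at least three longitudinal records and
GDS ≥ 5 at two or more visits, with the event placed at the first
qualifying visit (flag `event_at='second'` for the stricter reading);
otherwise samples are censored at their last visit. Counting-process rows
carry visit-level age and UPDRS-III; subjects qualifying at baseline have
no time at risk and are excluded from the survival analysis (they still
count in the binary outcome). The Cox model (sex fixed; age and UPDRS-III
time-dependent; Efron ties) is fitted by lifelines' counting-process
implementation, with PRS standardised so hazard ratios are per SD; the
test suite verifies the fitted coefficients against a brute-force
grid-search maximisation of the partial likelihood on small no-tie
fixtures. Kaplan-Meier curves stratify samples into PRS percentile bands
(default 0–5, 5–50, 50–95, 95–100 with 5–50 as reference; the exact
published cuts are not recorded, so round percentile bands are used) and
per-stratum hazard ratios come from the same adjusted Cox model with a
stratum indicator.

## The synthetic study

Generators are pure functions of `SimConfig` (one master seed; fixed
sub-stream offsets per data layer) and default to the study conditions:

* **Methylation** — 88 donors per region (80 in the recovery
  experiments), three regions sharing donors, 2000 probes with three
  planted modules of 200. Betas are a logistic squash of a Gaussian
  factor model: probe intercepts N(0, 1.25), loadings ±`loading_sd`
  (70% positive so the sign-oriented eigengene tracks the latent factor;
  the negative minority is what makes the unsigned network choice
  matter), per-region standard-normal latent factors, probe-specific
  covariate effects (age, sex, batch, neuronal proportion, PMI) and
  N(0, `noise_sd`) noise. The binary trait (prevalence 40%, matching
  reported depression prevalence in Parkinson's disease) thresholds a
  liability correlated with the first module's latent in the designated
  region; the latent-liability correlation is biserial-corrected so the
  *observable* eigengene-trait Spearman correlation targets
  `trait_module_r` (dichotomisation would otherwise attenuate it by
  φ(c)/√(p(1−p))). Logistic squashing keeps (0,1) support; the bimodal
  marginal distribution of real arrays is deliberately not modelled, so
  passing tests speak to the network machinery, not to array-specific
  artefacts. Trait-module probes are placed in three clusters on chr1 and
  annotated preferentially with genes from the module gene pool.
* **Cell reference** — negative-binomial counts (dispersion 2), six
  subtypes in three broad classes, 150 cells each. Every gene carries
  mild lognormal type modulation (sd 0.25; real nuclei show weak
  differential expression almost everywhere) and each subtype has 80
  markers with heterogeneous folds (lognormal around `marker_fold` = 5,
  sd 0.5). Only 40 of the designated subtype's markers sit in the module
  gene pool, so the controlled type's specificity tail also contains
  non-target genes and decile matching in the conditional test is
  meaningful.
* **Genetics** — 2000 variants at 50 kb spacing in AR(1) LD blocks of 20
  (latent correlation 0.8, thresholded at the allele-frequency quantile;
  allele frequencies U(0.1, 0.5)); 30 causal variants split
  inside/outside the module windows by `causal_in_window_frac`; liability
  with h² = 0.3. Summary statistics are direct plus LD-tagged effects —
  tagging uses the target panel's empirical block correlations; no
  separate discovery panel is simulated — with sampling noise at a
  discovery n of 20 000, chosen so per-variant power on the reduced panel
  resembles a large GWAS on millions of variants; ~8% of non-causal
  variants get ambiguous alleles and INFO is U(0.85, 1) (causal ≥ 0.95)
  so harmonisation has real work to do. GDS trajectories are a monotone
  binning, `GDS = clip(round(1.5 + 1.8·y), 0, 15)`, of a latent
  `y = 0.8·liability + 0.12·t + AR(1)` (φ = 0.6, stationary sd 0.8),
  calibrated once to ~45% lifetime GDS ≥ 5 prevalence and ~30% confirmed
  conversion; UPDRS-III rises ~1.5 points/year with noise.

Problem sizes throughout (2000 probes, 10-seed repetition, 10 000
bootstrap repetitions, 500-subject cohorts) are the package's desk-scale
conditions: large enough that every planted effect is comfortably
detectable and every null comfortably null, small enough to re-run
end-to-end in minutes.

## Numerical choices and degenerate inputs

Constant probes make correlations undefined and are rejected by the
network builders (the probe-significance test instead assigns p = 1 with
a warning). Bootstrap ties count as exceedances with a 1e-12 tolerance so
a degenerate null identical to the observation reports p ≈ 1 rather than
coin-flip p. Null standard deviations below 1e-12 are treated as zero
(sd_from_mean 0). Eigengene sign orientation falls back to the unsigned
vector when the mean module profile is constant. Clumping tie-breaks and
module relabelling are fully deterministic, so every pipeline output is a
pure function of the configuration and seed; cached artifacts are written
at full float precision so reruns are byte-identical.

## Known limitations

Real 450K arrays have bimodal betas, probe-type chemistry effects and
batch structure richer than a single categorical; none are modelled. The
simplified tree cut is not bit-compatible with dynamic tree cutting — it
is a stated surrogate validated on planted structure. The discovery GWAS
is emulated through the target panel's LD rather than an independent
panel, which slightly understates winner's-curse effects. EWCE here tests
one annotation level at a time and deduplicates gene symbols before
testing. Genetic PCs are computed without LD pruning. The GO resampling
test assumes the probe background is the analysis universe, as in the
array-bias-aware enrichment tools it mirrors.
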
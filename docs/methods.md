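# Methods

`concordpgs` implements a two-stage, concordance-filtered polygenic score
(PGS) workflow for a binary trait, exercised end to end on synthetic cohorts
with known ground truth. This note records the statistical model, the choices
made where the design was genuinely open, and what the synthetic conditions do
and do not establish about real data.

## The two-stage workflow

**Stage 0 — harmonization.** Each discovery study contributes per-SNV signed
z-scores (or beta/SE pairs converted to z = beta/SE at load). Palindromic
SNVs (allele pairs A/T or C/G) are excluded at load because their strand is
ambiguous across genotyping platforms. All studies are then re-oriented to the
first study's effect allele: a study storing the swapped pair has its z-sign
flipped; an allele pair that matches neither orientation is treated as a
cross-study mismatch and dropped. Strand flips (e.g. A/G recorded as T/C) are
*never* attempted — palindromic exclusion already removes the cases where
flipping would be ambiguous, and silent flipping risks sign errors. Studies
are matched by SNV identifier, not position, so no shared genome build is
assumed. Only SNVs present in every study survive, which guarantees the same
SNV set is scored in every cohort.

**Meta-analysis.** Case/control imbalance is absorbed by the effective sample
size N_eff = 4/(1/n_cases + 1/n_controls); a quantitative AUDIT-style study
derives its case count from the instrument's case threshold (scores of 12 or
more on the 0–40 scale) purely for the N_eff computation. The meta statistic
is the standard sample-size-weighted scheme

    w_i = sqrt(N_eff,i),   z_meta = Σ w_i z_i / sqrt(Σ w_i²),

with a two-sided normal p. No genomic-control correction and no
heterogeneity modelling are applied. The meta z doubles as the SNV's scoring
weight — the association z-score, not a per-allele log-OR.

**Concordance filter.** Only SNVs whose per-study z-scores all share one
strict sign are kept; z = 0 has no direction and fails. Under a complete null
with S independent studies the kept fraction is 2^(1−S) (25% for three
studies), so the filter discards three quarters of pure-noise SNVs while true
associations — which share a direction up to sampling noise — survive at a
much higher rate. This asymmetry is the entire point of the filter and is
verified by simulation in the test suite.

**Clumping (pruning and thresholding).** For each grid point
(p-threshold, r² cutoff, window) the concordant SNVs with meta-p at or below
the threshold are visited in ascending-p order; a SNV is accepted unless some
already-accepted SNV on the same chromosome within ±window has panel r² at or
above the cutoff. The default grid is 17 p-thresholds × r² ∈
{0.1,…,0.5} × windows {250, 500} kb = 170 weight sets; the loosest p entry
(">0.99") is implemented as 1.0, i.e. no p-filtering. Clumping dialects vary
across tools; this package uses deterministic index-SNV greedy clumping with
the tie-break (p, chromosome, position, snv_id), chosen because it is exactly
checkable against a brute-force replay (a property test runs the comparison
on hundreds of random instances). r² is the squared Pearson correlation of
genotype dosages with pairwise-complete handling of missing calls.

**Scoring.** PGS_i = Σ_j β_j · dosage_ij over the weight set, after aligning
each weight's effect allele to the dosage column (a swapped pair scores
2 − d). Missing dosages are mean-imputed per SNV. Scores are used raw: the
downstream dichotomization is rank-based and therefore invariant to affine
transforms; a standardization flag exists for reporting only.

**Risk groups and association.** Within each cohort separately (cases and
controls combined), the top 5–50% and bottom 5–45% of the PGS distribution
(5% steps) are dichotomized against the remaining sample; the flagged count
is ⌈fraction·N⌉ with ties at the cut broken by ascending individual id.
Association uses maximum-likelihood logistic regression of case status on
the group indicator with sex, ten ancestry principal components, and
genotyping-array dummies (most frequent array as reference) as covariates;
age is deliberately absent. Familial cohorts keep the same point estimates
but replace the covariance with the family-clustered sandwich (CR0 with the
standard G/(G−1)·(N−1)/(N−k) finite-sample factor, as fit by statsmodels);
with every family a singleton this reduces exactly to the plain fit. The
"GLMM via GEE with a random intercept" phrasing found in applied reports
conflates two estimators; the cluster-robust reading was chosen because it is
deterministic, assumption-light, and matches the GEE interpretation.
Confidence intervals are Wald on the log-odds scale throughout, matching the
symmetric-on-log "OR (95% CI)" convention; 2×2 tables with a zero cell get
the Haldane +0.5 correction and are flagged.

**Selection and testing.** The screening stage fits every weight set ×
threshold × direction (results computed once per distinct weight set, since
many grid points select identical SNVs). Exactly one weight set crosses to
stage 2: the one with the largest adjusted top-5% OR, except that among sets
whose top-5% confidence intervals overlap the best one's, the smallest SNV
count wins (parsimony). "Comparable" is formalized as CI overlap and is
configurable. No multiplicity correction is applied within the scan — the
two-stage design itself is the multiplicity control, and the testing-stage
estimates are unbiased because only one pre-selected score is evaluated
there. Sex-stratified and carrier-exclusion analyses re-derive percentile
thresholds within the analyzed subset.

## The synthetic-data generator

The generator produces every input the pipeline consumes, under one seed.

*Genotypes.* Block LD: within a block of `ld_block_size` consecutive SNVs,
each haplotype is an equicorrelated Gaussian latent (correlation
`within_block_r`) thresholded at the normal quantile of the SNV's MAF; two
independent haplotypes sum to a Binomial(2, maf) genotype. Blocks are
independent, span less than either clumping window internally, and sit 2 Mb
apart so no window bridges blocks. The implied between-SNV genotype
correlation follows the tetrachoric relation and is verified against a
numerical-integration oracle in the tests.

*Trait.* Liability-threshold model: liability = standardized-genotype score
(variance h²) + family-shared component (familial cohorts) + optional
large-effect protective carrier variant + Gaussian environment, thresholded
at the quantile of the prevalence. Causal effects are drawn normal and
normalized so Σ β²·2p(1−p) = h² exactly; LD among causal SNVs inflates the
realized genetic variance slightly above h², which is accepted and
documented rather than corrected. Covariates (sex, ten PCs, array label) are
generated independent of liability, so they are pure noise for the fits —
real ancestry structure is *not* emulated.

*Discovery GWAS.* Two modes. `full` simulates each cohort's genotypes and
computes per-SNV correlation-based score-test z-statistics — exact but only
desk-scale. `fast` (default) draws z ~ N(ncp, 1) with the liability-threshold
noncentrality ncp = b_marg · φ(t)/(K(1−K)) · √N_eff / 2, where b_marg folds
the block's reference-panel LD into the marginal effect; this makes
discovery cohorts of realistic size (hundreds of thousands) free. The two
modes agree in mean z in tests. Per-cohort multiplicative effect jitter
(sd 0.10) keeps directions shared while magnitudes vary — precisely the
structure the concordance filter exploits. Emitted summary statistics
include realistic representation noise: per-study allele swaps (with the
compensating z-sign flip), a small per-study missing fraction, and a small
corrupted-allele-pair fraction, so harmonization is genuinely exercised.

*Cohorts.* The default discovery trio mirrors a large unbalanced
case/control GWAS (34 658/167 346), a quantitative AUDIT-style GWAS
(n = 121 604, case threshold 12), and a very unbalanced biobank GWAS
(15 715/361 562) — in fast mode these sizes cost nothing. The screening
cohort (default 2000 in families of 4, family-shared liability variance 0.2)
is ascertained: case-rich families are sampled whole, and controls are then
subsampled within the selected families to a 70% case fraction, mimicking
cohorts recruited to study the disorder with strict control definitions
(family-of-4 sampling alone cannot reach such a case fraction). The testing
cohort (default 20 000, prevalence 5%) is a population sample. The protective
carrier variant (MAF 3%, large negative per-allele liability effect) is
carried in the phenotype truth and the carrier flag, but never enters the
SNV panel or the weights — enabling the carrier-exclusion analysis.

*Scale.* The default synthetic genome is 5000 SNVs (500 causal, h² = 0.5),
a deliberate desk-scale reduction of a genome-wide panel. One consequence:
with full-size discovery cohorts the estimated weights are far more precise
per causal SNV than in genome-scale data, so the synthetic PGS captures most
of the heritability and the top-5% odds ratios land near 10 rather than the
~2 that genome-wide studies report. Recovery checks are therefore
directional (top OR > 1, bottom OR < 1, calibrated nulls), not
magnitude-matching. At default scale the bottom-5% group of 1000 often
contains zero cases; its adjusted fit is then recorded missing and the
continuity-corrected table OR (well-defined at zero cells) carries the
directional check.

## Numerical and degenerate-input policy

- Duplicate SNV ids in an input file: keep first, warn. Rows with p outside
  (0, 1], non-ACGT or identical alleles, or non-finite z are dropped and
  counted in a plain-text load report.
- The Hardy-Weinberg exact test enumerates heterozygote counts conditional on
  allele counts in log-space and sums probabilities ≤ the observed one;
  monomorphic sites return p = 1 with a warning. The optional HWE filter
  (default threshold 1e-6) runs only when genotype counts are supplied.
- Perfect or quasi-perfect separation (|beta| > 30 or non-finite SEs) raises
  a named error in direct calls; inside the screening scan and stratified
  analyses a failed fit is recorded as missing and the scan continues.
- Constant PGS vectors make percentile groups undefined and are an error, as
  are cohorts below 20 individuals.
- All randomness flows from one integer seed through `numpy` Generators;
  reruns of the pipeline are byte-identical in every results table.

## Known limitations

- LD is block-equicorrelated with independent blocks; real human LD decay,
  long-range LD, and admixture are not modelled, and non-European-ancestry
  settings are out of scope.
- PCs are noise covariates; confounding by population structure is not
  represented, so the covariate adjustment is exercised mechanically, not
  substantively.
- The clumping dialect (greedy index-SNV, documented tie-breaks) is one of
  several in circulation; results at loose r² cutoffs can differ across
  dialects.
- Imputation quality, INFO-score filtering, INDELs, multi-allelic sites, and
  genome-build liftover are out of scope; dosages are taken as given.
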
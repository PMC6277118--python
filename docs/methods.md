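# Methods

This note documents the statistical models, algorithmic choices and known
limitations of the toolkit, in the order a cohort flows through it.

## Synthetic cohort model

The generator emulates the data structure of a multi-omic regulatory
study on a single synthetic chromosome (`chrS`, default 10 Mb — cis-window
logic needs coordinates, not genome context). Default cohort sizes mirror
the target design: 303 genotyped samples assayed for methylation, an
80-sample expression subset, and 74 samples in the expression–methylation
overlap; all are configurable.

**Genotypes.** Each variant draws a MAF uniformly from (0.05, 0.5] and
dosages as the sum of two Bernoulli allele draws — exact Hardy–Weinberg
sampling. Variants are independent (no LD; a stated non-goal), positions
uniform, and missingness, when requested, is missing-completely-at-random.

**Expression.** Gene value = baseline + β·dosage + N(0, σ), with
per-gene baselines N(8, 2) on the log2 scale. Planted genes take their
TSS uniformly within the cis window of their causal variant so the
pairing stage can find them.

**Methylation.** Beta values with CpG-level means drawn from a mixture
enriched for low and intermediate levels (45% low around 0.12, 30%
uniform 0.25–0.65, 25% high around 0.88), dispersed with concentration
κ = 50 by default: value ~ Beta(μκ, (1−μ)κ). This (mean, concentration)
parameterization is shared with the modality module. Planted mQTLs shift
the mean by the effect size per alternate allele; planted CpGs receive an
intermediate baseline (uniform 0.2–0.6) so typical shifts stay inside the
valid range, and any shift leaving (0.01, 0.99) is clipped with a
warning. The mean/variance profile is a loose qualitative match to
methylation arrays, not a fit to any dataset.

**Gap probes.** A configurable fraction of CpGs is generated as
genotype-determined clusters: three cluster centres 0.25 apart (driver
variant MAF ≥ 0.2 so all clusters are populated), values drawn at
concentration 800 and clamped to ±0.04 of their centre. Inter-cluster
gaps are therefore ≥ 0.17 by construction — comfortably above the 0.05
detection threshold, which is the intent: these mimic the strongly
clustered, variant-driven probes that gap detection targets.

**eQTM pairs.** Two generative regimes. *Linear* (cell-mixture): a latent
fraction f ~ Beta(a, b) of methylated cells drives both sides —
methylation = f plus beta noise at concentration 150, expression =
c0 + c1·f + N(0, 0.8); the sign of c1 sets the correlation direction.
*Bimodal* (two-state): a Bernoulli(ω) state picks methylation means
0.15/0.85 (κ = 50) and expression means 2/6 (SD 0.8) — roughly a 5σ
separation, a clear switch. Defaults are the conditions used throughout
the recovery experiments.

**Planted eQTMs in the bundled cohort.** `simulate_cohort` can couple a
gene's expression to a CpG's methylation (default 5 log2 units per beta
unit, random sign) and moves the CpG into the gene's ±100 kb window. The
CpG column is regenerated as a highly variable locus (mean uniform
0.3–0.6, concentration 8, beta SD ≈ 0.16): expression-coupled CpGs in
real cohorts sit in the top variability quartile, and the baseline
array-like CpGs (concentration 50, SD ≈ 0.06) carry too little variance
for any realistic slope to be detectable at n = 74.

**Bis-seq amplicons.** Per-read Bernoulli CpG calls at per-allele,
per-CpG probabilities; read counts exact. No read-level sequence or
alignment simulation.

All generators are bit-reproducible given (parameters, seed).

## cis-QTL and eQTM mapping

**Genotype QC.** Variants must pass call rate ≥ 95%, MAF ≥ 5%, and an
exact Hardy–Weinberg test at p ≥ 0.001. The HWE test enumerates all
heterozygote counts compatible with the observed allele pool and sums the
probabilities of configurations no more likely than observed.

**Cis pairing.** Closed windows: a pair is kept iff
|variant_pos − anchor_pos| ≤ W, with W = 1 Mb (eQTL, anchor = TSS),
75 kb (mQTL, anchor = CpG), 100 kb (eQTM, gene TSS vs CpG). Distance is
signed (variant − anchor), strand-ignorant; the score uses |distance| so
the sign convention is cosmetic.

**Association model.** OLS of phenotype on [intercept, covariates,
predictor], complete-case, two-sided t test on the predictor
coefficient. Covariates default to the K = 10 leading principal
components of the phenotype matrix — a hidden-factor adjustment in the
spirit of factor-analysis corrections, kept to plain PCs so the model is
fully reproducible from this package alone. Constant predictors or
phenotypes are flagged untestable rather than given p = 1.

**Permutation FDR.** For each target, phenotype values are permuted
across samples (covariates travel with the phenotype, so the
phenotype–covariate link is preserved while the phenotype–genotype link
breaks). The null statistic is the minimum nominal p over the target's
cis pairs per permutation — the best-association-per-phenotype scheme —
and the empirical p uses the +1-corrected estimator
(1 + #{null ≤ observed}) / (N + 1), which cannot return zero.
Benjamini–Hochberg is applied across targets' empirical p-values.
Internally the pass residualizes phenotype and predictors against the
covariates once (Frisch–Waugh), after which min-p per permutation equals
max |partial correlation|; this makes the permutation loop a single
matrix product per target. Samples are processed in canonical (sorted-id)
order so results are invariant to input row order. Missing phenotype
entries are dropped per target; missing dosages are mean-imputed for the
vectorized pass (with a warning) but handled complete-case in the
single-pair API.

**Filters and score.** Retention requires every *observed* genotype class
to hold ≥ 5% of samples (an alternative `any_nonref` rule — at least one
non-reference class ≥ 5% — is available because the written rule admits
both readings) and |slope| > 0.05 on the analyzed scale, strict, for all
three analysis types. The score (1 − p)·|β|/ln(|d| + 2) uses the natural
log; it is finite for d = 0 (denominator ln 2), zero iff p = 1 or β = 0,
monotone in each argument.

## Probe QC

A probe is *excluded* when a variant with MAF > 1% overlaps the
interrogated CpG (either base of the dinucleotide) or lies within 20 bp
upstream of it — upstream meaning along the probe body toward the 3' end:
lower coordinates for plus-strand probes, higher for minus-strand, plus
the single-base-extension position for type I probes (both the CpG-based
and extension-based windows are checked since the convention is
ambiguous). Variants whose allele pair is {C, T} *on the probe strand*
are exempt: after bisulfite conversion they cannot alter hybridization.
Cross-reactive probes (blacklist membership) are likewise excluded.

Gap signals only *flag*: sorted beta values are split wherever
consecutive values differ by more than 0.05 (the conventional gap
threshold of the reference implementation of this detector), groups of
size ≤ ceil(0.01·n) are discarded as outlier-driven, and a gap requires
≥ 2 surviving groups. Association tables can be split into a stringent
set (excluded probes removed) and an annotated full table (everything
kept, flagged).

## Modality models

Expression: y_i ~ N(μ, 1/τ) or ω·N(μ1, 1/τ) + (1−ω)·N(μ2, 1/τ) with
shared precision. Priors: μ ~ N(0, sd 100) truncated to [0, ∞) (applied
to both mixture means), τ ~ Gamma(0.01, rate 0.01), ω ~ Beta(1,1)
restricted to [0.1, 0.9]. Because the mean prior is nonnegative, inputs
with negative values are shifted up by −min(y) before fitting and the
reported means shifted back; the likelihood is translation-invariant so
BICs are unaffected, and the shift is recorded on the fit.

Methylation: y_i ~ Beta(μκ, (1−μ)κ) or the two-component mixture with
shared κ. Priors: μ ~ Beta(1,1), κ ~ Gamma(0.01, 0.01), ω ~ Beta(1,1)
restricted to [0.2, 0.8]. Values at exactly 0 or 1 are clamped to
[1e-4, 1−1e-4] before likelihood evaluation.

**Sampler.** Bespoke Gibbs with latent component indicators. Conjugate
updates where they exist: truncated-normal draws for expression means
(inverse-CDF), Gamma for τ, Beta-restricted-to-the-box for ω (inverse
CDF via the regularized incomplete beta function). The beta-model μ and
κ have no conjugate updates and use random-walk Metropolis within Gibbs
(logit scale for μ, log scale for κ), with step sizes adapted toward
~30% acceptance during burn-in and frozen afterwards so the post-burn-in
chain is a fixed Markov kernel. Defaults: 2 chains × 4000 iterations,
1000 burn-in; convergence is monitored by split-chain potential scale
reduction (threshold 1.1) on the location parameter, reported as a
`converged` flag rather than an error. Label switching is resolved by
relabelling every stored draw to μ1 < μ2 (masses follow); the mass boxes
are symmetric, so relabelled masses stay inside them.

**Model choice.** BIC = k·ln(n) − 2·logLik with k = 2 (unimodal) or 4
(bimodal), the log-likelihood evaluated at plug-in posterior means (a MAP
plug-in would be a drop-in alternative; posterior means are the stabler
summary of well-mixed chains). Ties go to the unimodal model (parsimony).
An eQTM pair is *linear* iff both sides are unimodal, *bimodal* iff both
are bimodal, and *discordant* otherwise — the mixed cell has no standard
name, so this package names it. The correlation sign comes from the OLS
slope of expression on methylation.

At the experiment scale used in the acceptance checks (n = 100 per pair,
2 chains × 2000 iterations), classification accuracy on both planted
classes exceeds 90% and a full two-sided fit takes ~0.3 s.

## Enrichment, π1, variability

**Enrichment.** X = overlap of candidates with the feature (interval
features use BED semantics — 0-based half-open, a locus at 1-based p
overlaps [s, e) iff s ≤ p−1 < e; label features are set membership).
Each of k permutations draws |candidates| loci from the universe without
replacement. The reported empirical p is #{Y_k > X}/k — kept as the
primary definition for fidelity to the procedure it reproduces — with a
+1-corrected variant (1 + #{Y_k ≥ X})/(k + 1) also returned since the
primary formula can yield exactly zero. obs/exp = X / mean(Y). A feature
covering the whole universe is flagged degenerate.

**π1.** π0(λ) = #{p > λ} / (m(1−λ)) on the grid λ = 0.05…0.95 step
0.05; π̂0 is a cubic least-squares smooth of this curve evaluated at
max λ, clipped to [0, 1], and π1 = 1 − π̂0. The fit is weighted by
√(1−λ): Var[π0(λ)] grows like 1/(1−λ), so these are inverse-SD weights;
they cut the null sampling error of the extrapolated endpoint roughly in
half relative to an unweighted fit without biasing alternatives.
Degenerate fits fall back to π0(0.5). Note π1 can only count alternative
mass below the top of the grid: an alternative with appreciable mass
above λ = 0.95 is intrinsically undercounted.

**Variability.** Per-feature MAD across samples (scaling constant
configurable: 1.0 raw default, 1.4826 for normal consistency), quartile
boundaries of the MAD distribution assigning classes none/low/medium/high.
Quartiles are computed over all features including constant (MAD 0) ones.

## ASM calling

Per-read fractional methylation is the mean over observed CpG calls
(missing calls ignored). Each of 1000 bootstrap iterations subsamples 20
reads per allele without replacement and applies a two-sample Wilcoxon
rank-sum test (normal approximation with tie and continuity correction —
exact enumeration is kept as a test oracle); the amplicon statistic is
the **median** p and median ΔMeth over iterations. Subsampling indexes the
*sorted* per-read fractions, and with equal allele coverage the same
index draw is applied to both alleles; this coupling makes the results
exactly invariant to read order and exactly antisymmetric under an
allele-label swap, at no cost to the marginal distribution of either
subsample. Testing requires ≥ 100 total fragments and ≥ 20 reads per
allele. An amplicon is hap-ASM when |ΔMeth| > 0.20, more than 3 CpGs show
a full-data per-allele difference > 0.20 (the amplicon-level threshold
reused per CpG, and computed on the full data rather than per bootstrap
draw), and median p < 0.05 — all strict inequalities. The binomial
allele-bias test (exact, two-sided against 0.5) asks whether the
hypomethylated state tracks one haplotype across heterozygous samples;
imprinting, which ignores haplotype, predicts no bias.

## What the synthetic experiments do and do not show

Passing recovery and calibration tests demonstrates that the estimators
are correct under their own assumptions: independent variants, additive
effects, homoscedastic normal or beta noise, no batch structure, no cell
composition confounding beyond the explicit cell-mixture eQTM model.
Real cohorts violate several of these (LD, batch effects, tissue
heterogeneity), so synthetic recovery rates are upper bounds, not
forecasts. Problem sizes in tests and the acceptance script (hundreds of
targets, hundreds of replicates, reduced 2 × 2000 MCMC) are chosen to
estimate each rate to a few percent Monte Carlo error while keeping the
full run in minutes on one CPU.

## Known limitations

- No trans effects, LD structure, conditional/multi-variant models, or
  beta-approximation speedups for permutation p-values.
- Mixtures are limited to two components; no covariate-adjusted mixtures
  or cell-type deconvolution.
- Enrichment nulls are unmatched (no GC/distance-matched sampling).
- The vectorized permutation pass mean-imputes missing dosages; cohorts
  with heavy genotype missingness should pre-filter on call rate (the
  QC default) or accept the approximation.
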
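# Methods

## Model

The regression of pseudophenotypes on marker covariates is

y = μ + Σᵢ δᵢ zᵢ aᵢ + e,

where y holds one deregressed-EBV-like value (DEBV) per genotyped
animal on the log tick-count scale, zᵢ is the centered dosage covariate
of SNP i, aᵢ its allele substitution effect, δᵢ ∈ {0,1} an inclusion
indicator and e ~ N(0, I σ²ₑ).  The three samplers differ only in the
prior on (δᵢ, σ²ᵢ):

* **BayesA** — δᵢ ≡ 1; locus-specific σ²ᵢ ~ scaled-inv-χ²(ν_a, S_a).
* **BayesB(π)** — P(δᵢ=0) = π fixed; locus-specific variances as above.
* **BayesCπ** — common effect variance for all included SNPs; π sampled
  from its Beta full conditional (uniform prior), started at 0.5.

Sampling is single-site Gibbs.  For BayesB/Cπ the inclusion indicator is
drawn from the marginal conditional of rᵢ = zᵢ′e₋ᵢ after integrating
the effect (variances zᵢ′zᵢσ²ₑ vs zᵢ′zᵢσ²ₑ + (zᵢ′zᵢ)²σ²ᵢ); an included
effect is then drawn from its normal full conditional; locus variances
from scaled-inv-χ²(ν_a+δᵢ, (S_aν_a + aᵢ²)/(ν_a+δᵢ)); the residual
variance from its scaled-inv-χ² full conditional.  A fixed mean is
fitted by default (DEBV are approximately but not exactly centered) and
can be disabled.  The whole update sweep runs in a numba kernel; chains
are seeded and bit-reproducible, and at every iteration the maintained
residual satisfies y = μ + Zα + e to machine precision.

Per kept sample the genomic heritability is h² = V_g/(V_g + σ²ₑ) with
V_g the variance across individuals of the genomic values Zα.  Per-SNP
posterior products: model frequency (MF), t-like statistic
(TL = |mean| / SD of the effect over inclusion samples, undefined below
two inclusion samples), posterior mean effect over all kept samples,
and a standardized effect (posterior mean × SD(covariate)/SD(response)
— a reporting convention only).

### Priors and their scales

Defaults are the printed dispersion priors for this trait:
σ²ᵢ ~ scaled-inv-χ²(4, 0.0091) (mean 0.0182) and
σ²ₑ ~ scaled-inv-χ²(10, 0.0572) (mean 0.0715), appropriate for
log-count-scale phenotypes (variance ≈ 0.33) analysed with π = 0.99.
When no previous variance estimates exist, `PriorSpec.from_data` sets
the scales from the data: the genetic-variance guess h²·var(y) is
apportioned over the (1−π) fraction of markers fitted per cycle.

Whole-genome BayesA (π = 0) needs care at desk scale: allocating the
genetic variance equally over all markers leaves the per-locus prior so
permissive that thousands of null loci absorb residual noise into Zα
and inflate h².  `sparsity_informed_bayesa_prior` therefore runs a
pilot BayesCπ chain (the same role BayesCπ plays in the original
workflow, where its posterior π guided the choice of π for BayesB) and
sets the BayesA base scale to the null-locus level (1−π̂)·V̂g/Σvar(z);
the heavy-tailed ν_a = 4 prior lets QTL-linked markers escape the
floor.  Locus variances are initialized at the allocation scale, not at
the base scale — starting a sampler at a near-zero locus variance traps
effects at zero (the variance cannot grow until the effect does, and
vice versa).

### Genotype coding

Internally 0/1/2 dosages, centered per column.  The −10/0/10 coding used
by GenSel-class software is expressed through the `coding_center`/
`coding_scale` descriptor; rescaling the coding by c with the locus
prior scale divided by c² reproduces the identical chain (effects ×1/c,
MF/TL/h²/fitted values unchanged), which the tests verify at 1e−6 with
matched seeds.

### Convergence

Geweke z-scores compare the means of the first 10% and last 50% of each
monitored trace (σ²ₑ, V_g, h², π), with spectral variances from a
Bartlett lag window (lag ≈ 4(n/100)^{2/9}).  Constant traces return
z = 0 with a degenerate flag.

## Windows and tag selection

SNPs map to half-open 1-Mb bins [k·10⁶+1, (k+1)·10⁶] on 1-based
positions; only non-empty windows are instantiated and numbered in
physical map order.  Per kept sample the window share is
var(Z_w α_w)/var(Zα) across individuals (samples with zero total
genomic variance are skipped and counted).  Because windows are in LD,
raw shares need not sum exactly to 100; `numerator="covariance"`
(cov(u_w, u_total)/var(u_total)) splits the covariance and sums to 100
exactly.  Per-sample averaging is the default; a posterior-mean-effect
variant exists behind a flag.  Top windows satisfy
pct ≥ multiplier × 100/n_windows with multiplier 5 ("at least" read as
≥).

Tag selection is the four-step rule: (1) maximum-MF SNP per top window,
ties broken by higher TL, then higher MAF, then lower position; the
minimum MF over these top SNPs becomes the threshold; (2) add SNPs in
top windows with MF strictly above it; (3) take the minimum defined TL
over the pre-selected set (top SNPs and MF additions alike) and add
SNPs with TL strictly above it; (4) resolve r² > 0.4 pairs (composite
r²: squared Pearson correlation of dosages) in descending r² order,
always dropping the lower-MAF member (MAF tie: higher position), until
no pair offends.  Top SNPs are not protected from pruning by default
(the printed rule keeps max-MAF unconditionally); a protect flag
exists.  All tie-breaks are deterministic.

## Cross-validation and accuracy

Groups come from a seeded random split (sizes differing by ≤1) or from
K-means on the top ten principal components of the VanRaden method-1
GRM (10 restarts; re-seeded on the degenerate empty-cluster case).
Each fold re-runs discovery (BayesB π = 0.99), window calling and tag
selection on its four training groups only, refits the panel effects
with BayesA on the training data, and computes DGVⱼ = Σᵢ z_jᵢ âᵢ for
the held-out group — test individuals never touch training (asserted by
disjoint id-set hashes).

The within-group accuracy estimator is cor(DGV, DEBV)/√r.  Since
cor(DGV, debv) = cor(DGV, u)·cor(u, debv) and cor(u, debv) = √r for a
pseudophenotype of reliability r, dividing by √r recovers the accuracy
of the DGV as predictors of true breeding values; r comes from the
pseudophenotype table's weight column.  When reliabilities are absent
the divisor falls back to the training-run posterior mean genomic h² of
the refit model — a known understatement whenever the panel captures
only part of the genetic variance, which inflates the estimate.  When
the discovery run itself finds essentially no heritable signal
(posterior h² < 0.02) the rescaling is meaningless; such folds report
the raw correlation and are flagged.  Pooling uses inverse-variance
weights from Fisher-z standard errors, w_c = n_c − 3.

## Synthetic populations

The generator emulates the statistical structure the analysis assumes,
at desk scale (defaults 1000 animals × 2000 SNPs on five 10-Mb
chromosomes):

* **LD** — haplotypes from a Gaussian copula: a latent AR(1) field with
  lag correlation exp(−Δbp/ld_decay_bp) (default decay 100 kb),
  thresholded at per-SNP allele frequencies.  Forward-in-time
  simulation would be overkill for controllable pairwise LD.
* **Admixture** — two ancestral pools diverged by a Balding–Nichols
  Fst-like parameter (default 0.1); each animal draws a zebu proportion
  uniform on the configured range (default 0–0.4) and mixes pool
  frequencies accordingly.  Ancestral frequencies stay in [0.05, 0.95],
  keeping sample MAF away from fixation before QC.
* **Architecture** — n_qtl (default 10) causal loci with heavy-tailed
  gamma(0.4) effect magnitudes and random signs; by default the QTL are
  simulated jointly with the markers but withheld from the returned
  panel, so markers tag them through incomplete LD, as on a real chip.
  Oracle tests that probe estimator behaviour (not LD completeness) set
  `qtl_genotyped=True`.
* **Trait scale** — effects are rescaled so var(tbv) = h²·0.33, the
  phenotypic variance of log(tick count + 1) records, which keeps the
  printed dispersion priors on the right scale.  Records (2–3 per
  animal, default 3) follow a repeatability model with repeatability
  0.30; a zero target h² zeroes the planted effects (documented
  degenerate case).  Raw counts are recoverable as exp(y) − 1 but are
  not produced by default.
* **Pseudophenotypes** — DEBV = tbv + noise with
  var(noise) = var(tbv)(1−r)/r, so cor(debv, tbv)² ≈ r (default
  reliability 0.5, a free choice: the study does not report DEBV
  reliabilities).  Pedigree BLUP and exact deregression weights are not
  emulated; the DEBV enter downstream stages only as a response with a
  known reliability, which this construction reproduces.  Zero-variance
  tbv yields flagged pure-noise DEBV.

What passing tests on these populations do **not** show: behaviour under
real pedigree structure, contemporary-group fixed effects, genotyping
error, ascertainment bias of chip SNPs, or the many-small-QTL regime of
the real trait (desk-scale window counts force a concentrated
architecture so that top windows exist at the 5× threshold).

## Quality control

Single pass, individuals before SNPs (the order is recorded in the
report; the original order is unstated upstream): call rate < 0.90
(strict), heterozygosity outside mean ± 3 SD, then pairwise genotype
concordance > 0.995 over jointly non-missing SNPs (the higher-call-rate
member is kept).  SNPs: call rate < 0.98, MAF < 0.03, 1-df HWE χ²
P < 1e−7 (no continuity correction; monomorphic SNPs fail MAF first),
then redundancy groups (same chromosome+position or |r| > 0.98, closed
transitively) keep the max-MAF member, ties to the lower position.
Every removed item carries exactly one primary reason, so planted
violations are countable.  Missing entries are filled with the per-SNP
expected dosage 2p, left fractional; a pedigree/haplotype imputer is
unnecessary at ≤2% sporadic missingness and mean imputation preserves
the regression expectation.  No sex-chromosome checks (none are
modelled).

## Problem sizes and numerics

The default test run exercises the full pipeline at 1000×2000 with
5000-iteration chains (about a minute with the numba kernel) and the
statistical property suites at 500–1000 animals with 800–2000-iteration
chains over 3–5 seeds; trend assertions (accuracy orderings, grouping
comparisons) are made on means over seeds, not per seed.  Thinning
defaults to 1 for plain chains; window variance and cross-validation
use thin 5 to keep effect-trace matrices small.  Accuracies are clamped
to [−1, 1] with a flag; degenerate inputs (constant traces, zero
variance columns, undefined TL) yield flagged NaN rather than errors
wherever a downstream rule can proceed without them.
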
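# Methods

This note records the statistical models, defaults, and design choices
behind `devqtl`, and what the synthetic-data generator does and does
not emulate.

## Cohort model

Samples carry a post-conception age in days, a developmental period
1–12, an epoch (0 ↔ periods 1–2, 1 ↔ 3–5, 2 ↔ 6–8, 3 ↔ 9–12), and a
stage (prenatal = periods 1–6, transitional = period 7, postnatal =
periods 8–12). The default cohort is 176 samples: 112 prenatal, 4
transitional, 60 postnatal, matching the three analysis cuts the eQTL
scan uses (complete / prenatal / postnatal; period 7 belongs to the
complete cut only). Period boundaries on the age axis are
configuration, not hard-coded biology: the generator assigns periods
directly and only requires the per-period age intervals to be ordered
and non-overlapping.

## Expression generation and preparation

Generated expression is Gaussian on the log₂CPM scale: gene baseline
(N(2.5, 2²)) + group polynomial of standardized log₂ age + planted
eQTL dosage effects + optional sex effect + N(0, σ²) noise, inverted to
integer counts through the pseudocount transform against a nominal
library size (default 3×10⁷). The default trajectory mixture has three
groups — rising, falling, flat — with weights (0.29, 0.22, 0.49) chosen
to match the observed proportions of rising/falling/non-transitional
genes in developing cortex, and σ = 0.5 log₂ units, a typical residual
SD for well-expressed genes in bulk brain RNA-seq. The default sex
effect on autosomal genes is 0 (no published magnitude to emulate); a
config hook exists.

Counts are Gaussian-on-log rather than negative binomial deliberately:
every downstream stage consumes log₂CPM, so Gaussian-on-log is exactly
the structure those stages assume, and count-level dispersion modelling
would add realism none of the tested procedures use.

Preparation follows the documented order: CPM → expressed-gene filter
(CPM ≥ 1 in ≥ 50% of samples of one sex in one period; the fraction
test is exact, so 3-of-6 passes) → log₂CPM with the (c + 0.5)/(L + 1)
pseudocount → hidden-factor adjustment. Adjustment regresses each gene
on period (categorical) + sex, removes the top `n_hidden` principal
components of the residual matrix, and keeps the period/sex signal,
which re-enters the eQTL model as covariates. This is a transparent
surrogate for hidden-covariate/surrogate-variable pipelines: the
downstream requirement is only "technical sample-level structure
removed", and a residual PCA is testable against planted factors.

Two properties of this surrogate deserve flagging. First, removing the
top n PCs is not idempotent in general — a second pass removes
components n+1..2n; exact idempotence holds only when the residual has
rank ≤ n (the regime the test suite exercises). Second, at small gene
counts the residual PCs can latch onto individual high-variance genes,
including planted eQTL targets: with 120 genes and n_hidden = 5,
planted effects of 0.8 attenuated to ~0.65. The ratio n_hidden/genes
should be kept near real-data practice (tens of hidden factors against
tens of thousands of genes); synthetic studies here default to
n_hidden ≈ 2–5 per 10²–10³ genes.

## Genotypes

Variants are biallelic with allele frequency uniform in a configured
MAF range and genotypes drawn in Hardy–Weinberg equilibrium by double
thresholding of latent Gaussians. Optional LD is block-diagonal:
variants in a block share an allele frequency and a compound-symmetric
latent correlation solved from the bivariate-normal orthant probability
so the allele-level correlation equals √r² exactly in expectation. Real
LD decay, recombination maps, and demography are out of scope. The HWE
filter uses an exact conditional test with the mid-p correction (the
plain exact test is conservative; mid-p restores mean 0.5 under the
null). Its p-values are discrete, so calibration checks compare the KS
distance and mean rather than a KS p-value.

## Association scan

Per pair: OLS of adjusted expression on dosage + intercept + period
(categorical) + sex + 5 ancestry PCs over the cut's samples,
implemented by Frisch–Waugh–Lovell residualization (expression and
dosage projected off the covariate design once per cut, then per-pair
closed-form slope/SE/t). This is algebraically identical to the full
design — the acceptance suite verifies equality with normal-equation
OLS to 10⁻⁸ relative error. Pairs with constant dosage in a cut get
missing statistics and are excluded from the BH family, which is
computed per cut over all tested pairs.

Genomic control: λ = median(χ²₁ quantile of p) / 0.4549 over 500
same-chromosome pairs with TSS-to-variant distance in [10, 100] Mb
(TSS anchoring chosen for symmetry with the signed TSS-distance
convention: positive downstream, negative upstream by strand), repeated
100 times. On a 2,000-gene/20,000-variant null cohort the median λ is
1.00–1.02.

## Trajectory mixture

Each gene's IQR-normalized profile is one observation sequence;
component k is a degree-4 polynomial of standardized log₂ age with its
own variance σ_k² (homoscedastic across samples, independent given the
component). EM with random-responsibility initialization, best of
`n_starts` = 10 restarts, relative log-likelihood tolerance 10⁻⁶, and
pruning of components whose prior falls below `min_prior` = 0.05
(after a prune the likelihood trace restarts, since the model class
changed). Epoch-0 samples are excluded from fitting via an explicit
filter — with very few early-embryonic samples they would bias the
curve ends. Model-order selection: AIC/BIC with K·(degree+2) + (K−1)
free parameters; argmin BIC, ties to the smaller K. Rising/falling
labels use the epoch-3 − epoch-1 mean fitted contrast with threshold
δ = 0.5 normalized units — a numeric stand-in for by-eye labelling;
hard assignment is argmax responsibility with ties broken toward
non-transitional, then falling, then rising.

## Temporal classification

The Z-test FDR family is the set of top pairs (one per eGene) — the
minimal coherent family for a statistic defined only on top pairs. The
five categories are evaluated in order (constant, prenatal-predominant,
postnatal-predominant, then trending by sign of β_pre − β_post, exact
ties to postnatal-trending); the primary three are mutually exclusive
by construction, so the order is cosmetic. "Same direction of effect"
for the constant rule uses point-estimate signs. The differential-
variance F-test residualizes each stage separately on period + sex +
5 PCs and doubles the smaller F tail for a two-sided p.

## GWAS integration

Supervised pruning processes SNPs in ascending GWAS p and keeps a SNP
unless it has r² > 0.7 with an already-kept SNP within 500 kb —
deterministic given the position/id tie-break, so input order is
irrelevant. Matching bins are MAF deciles × gene-density deciles
(density = number of genes whose ±1 Mb cis window contains the
variant), computed over the tested universe after configured region
exclusions (an HLA analogue; empty by default in simulation). Null
sets replace each GWAS SNP by a uniform draw from its bin excluding
itself, independently across SNPs and permutations; the empirical p is
add-one, (r + 1)/(n_perm + 1), counting null proportions ≥ the
observed. This p is conservative when proportion ties occur (the
proportion grid is 1/|set|); at 2,000 permutations and ≥40 SNPs it is
uniform to within KS sampling error under an exchangeable null.

Colocalization uses Wakefield log-ABFs, log ABF = ½·log(V/(V+W)) +
z²W/(2(V+W)) with V = se² and prior effect variance W = 0.15² (the
quantitative-trait convention), priors (p1, p2, p12) =
(10⁻⁴, 10⁻⁴, 10⁻⁵), and log-sum-exp accumulation of the five
hypothesis sums. Note the posteriors are not invariant to rescaling
beta and se jointly per SNP — the ABF depends on V relative to W, not
on z alone — so inputs must be on the per-allele effect scale matching
W. Gene-set Fisher tests take the expressed-gene universe as
background and drop trait genes outside it; correction is Bonferroni
by the stated family size, or BH across a family run through
`gene_set_fet_table`.

## Problem sizes

Test-suite simulations use 100–300 genes, 10²–10³ variants and the
176-sample design for recovery checks, and a 2,000-gene /
20,000-variant cohort for the calibration and type-I-error checks —
sizes at which every Monte Carlo bound asserted (assignment accuracy,
λ band, KS uniformity, fold recovery) has comfortable margin while the
whole suite stays interactive.

## What passing tests do and do not show

The generator produces exactly the structure the methods assume:
Gaussian log-scale noise, HWE genotypes, block LD, polynomial
trajectories, additive stage-specific cis effects. Passing recovery
tests therefore demonstrate internal correctness and calibration, not
robustness to real-data pathologies — count overdispersion, batch
structure correlated with age, LD decay, allelic heterogeneity,
cross-chromosome structure, or sample contamination are all absent by
construction. The five-category classifier in particular inherits the
power asymmetry of the 112/60 split: postnatal-predominant effects are
detected at lower rates than prenatal ones at equal effect size.

## Known limitations

- Hidden-factor adjustment is a residual-PCA surrogate, not HCP/SVA;
  users comparing against pipelines that subtract 20 HCP + 2 SVA
  components should expect small numeric differences.
- Single-causal-variant colocalization only; no fine-mapping or
  multi-signal decomposition.
- No mixed-model/kinship adjustment in the scan; trans-eQTLs and
  conditional secondary signals are out of scope.
- The LOESS-style marker profiles use a local-linear tricube smoother
  with a pointwise normal band; it is a visualization aid, not an
  inferential tool.
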
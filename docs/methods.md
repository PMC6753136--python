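# Methods

`meqtlkit` implements the analysis chain of a family-based, whole-blood
methylation-QTL study: variance-components heritability of CpG methylation,
two-step cis/trans meQTL mapping, two-sample Mendelian randomization (MR) of
CpGs on outcome traits, Bayesian colocalization of methylation and
expression signals, eQTM scanning, trans-meQTL hotspot detection, and
annotation enrichment. A synthetic-cohort generator with recorded ground
truth makes every stage testable without restricted genotype or methylation
data. This note documents the models, the defaults and why they were
chosen, the numerics, and what the synthetic validation does and does not
establish.

## Variance-components model of CpG methylation

Each CpG's beta value vector `y` (n samples) is modeled as

    y ~ N(Xb, σ²_A·K + σ²_h·H + σ²_e·I)

where `K` is the additive relationship matrix (co-ancestry 0.5 for
parent–offspring and full-sib pairs, 1 on the diagonal, 0 otherwise —
coefficients used directly as covariance multipliers) and `H` the
shared-household matrix (1 within a family including the diagonal). Narrow
heritability is `h² = σ²_A / (σ²_A + σ²_h + σ²_e)` and the household effect
is the analogous σ²_h fraction. The same engine fitted with a genomic
relationship matrix `G` (standard GRM,
`G_ij = (1/m) Σ_k (g_ik−2p_k)(g_jk−2p_k)/(2p_k(1−p_k))`) estimates the
variance a SNP set explains, on an unrelated subset (one member per family).

**Fitting.** Restricted maximum likelihood with 20
expectation-maximization warm-start iterations followed by
average-information updates, step-halved so the restricted log-likelihood
never decreases over accepted AI steps. Convergence when the largest
component change is below `tol × var(y)` (default `tol = 1e-6`; the
relative form makes convergence scale-free — beta-value variances are of
order 1e-3) or the relative log-likelihood change is below 1e-10. Negative
proposals are clamped at 1e-10 and the fit flagged `boundary`.

**Block structure.** Pedigree covariance matrices are block diagonal by
family. The solver detects blocks from the joint sparsity of the covariance
list and batches all linear algebra per block size, so a scan over
thousands of CpGs in a cohort of hundreds of families costs milliseconds
per CpG. Dense matrices (a GRM) degrade gracefully to a single block.

**Identifiability.** When the covariance components are linearly dependent
— kinship equal to the identity, or a sibling-only pedigree where the
kinship block is exactly `0.5·I + 0.5·J` (J = household block) — the split
between components is arbitrary. The engine detects rank deficiency of the
components' Gram matrix up front and flags the fit (`identifiable=False`)
instead of reporting an arbitrary decomposition. Consequently, h² recovery
on sib-quad cohorts is validated with the kinship-only model (the
identifiable model for that design); joint additive + household recovery is
validated on nuclear families, where parent–parent pairs break the
collinearity.

## Two-step meQTL mapping

Step one pre-adjusts methylation for fixed covariates and the pedigree (the
mixed model's conditional residuals, `σ̂²_e P y`) and scans residuals
against SNP dosages with vectorized simple regression, keeping pairs below
liberal prefilters: p < 1e-6 for cis, p < 1e-10 for trans. Step two refits
retained pairs with the full mixed model (SNP as fixed effect, kinship
random effect) and applies Bonferroni thresholds `α/n_cis` and `α/n_trans`
from the configured test universes (the canonical universes of 2.5e9 cis
and 3.5e12 trans pairs give 2e-11 and 1.43e-14); realized test counts are
used when the universes are not supplied.

Pair classes by SNP–CpG distance (positions are 1-based, windows inclusive):
cis within 1 Mb; long-range cis in (1 Mb, 5 Mb] on the same chromosome —
excluded from both significance sets; intrachromosomal trans beyond 5 Mb;
interchromosomal trans. Long-range-cis pairs are admitted at the trans
prefilter and removed at the significance step, matching the order in which
a genome-wide scan discovers and then filters them.

When the kinship matrix is numerically the identity the mixed model's limit
is ordinary least squares; residualization and refit take the exact OLS
path there (this is also what makes two-step results equal direct per-pair
regression to 1e-6 on unrelated cohorts, the engine's oracle-equivalence
check).

LD pruning is greedy in ascending p (ties: position, then id), retaining a
SNP iff its dosage r² with every retained SNP is below the threshold
(0.2 for locus counting, 0.01 for MR instruments, configurable). The
genomic inflation factor is `λ = median(χ²₁ quantiles of 1−p) / 0.45494`.

## Two-sample Mendelian randomization

Instruments for a CpG are its independent cis-meQTLs (LD r² < 0.01, lowest
meQTL p per block); at least three are required. Outcome effects are
harmonized to the exposure effect allele: matching alleles kept, swapped
alleles sign-flipped, palindromic (A/T, C/G) variants with MAF in
[0.42, 0.58] dropped as strand-ambiguous (an implementation choice — with
MAF near 0.5 the strand cannot be inferred), unmatched ids dropped.

The causal estimate is fixed-effect inverse-variance-weighted (IVW) over
per-IV Wald ratios `β_j = Γ_j/γ_j` with first-order standard errors
`se_j = se_Γj/|γ_j|` (second-order terms are negligible for the strong
instruments required here); fixed-effect IVW is algebraically identical to
weighted through-origin regression of Γ on γ, which the tests assert. A
multiplicative random-effects scaling `se × max(1, √(Q/(J−1)))` is
available by flag, but because downstream filtering requires the
heterogeneity test to pass, the two nearly coincide on reported results.

Diagnostics: Cochran's Q (χ², J−1 df) and the MR-Egger intercept (weighted
regression with γ oriented positive, intercept t-test with J−2 df). While
either p-value is below 0.05 the IV with the largest Q contribution `q_j`
is removed and the fit repeated — `q_j` is the standard single-IV
outlyingness measure and needs no extra machinery; the loop stops before
the count drops under three and records the exclusion order. An Egger fit
that is undefined (identical exposure effects) counts as a failed
diagnostic rather than an error.

Correlated CpGs within 2 Mb: clusters at r² ≥ 0.5 collapse to the member
with the lowest MR p (transitive clustering); groups with 0 < r² < 0.5 go
to multivariable MR — weighted regression of Γ on the matrix of per-CpG γ
without intercept — which reduces exactly to IVW for a single exposure.
Binary outcomes report OR = exp(θ) with exp(θ ± 1.96·se) intervals. The
expression path is the same engine with cis-eQTL instruments and a
single-IV Wald-ratio fallback.

## Colocalization

Per SNP and trait, the Wakefield log approximate Bayes factor is
`0.5·ln(1−r) + 0.5·z²·r` with `z = β/se` and `r = W/(W+se²)`; the prior
effect standard deviation defaults to `W^0.5 = 0.15` (the method's
conventional quantitative-trait default). Hypothesis sums over
single-causal-variant configurations are computed with log-sum-exp:
S0 = 1, S1 = p1·Σᵢ ABF1ᵢ, S2 = p2·Σᵢ ABF2ᵢ,
S3 = p1·p2·(Σᵢ ABF1ᵢ · Σⱼ ABF2ⱼ − Σᵢ ABF1ᵢ·ABF2ᵢ),
S4 = p12·Σᵢ ABF1ᵢ·ABF2ᵢ; posteriors are the normalized sums. S3 is exactly
zero for a single-SNP region and clamped at zero under floating
cancellation (logged). Default priors: p1 = 2e-11, p2 = 1e-7,
p12 = 0.1·p1; the conventional 1e-4/1e-4/1e-5 preset is provided. A region
enters the analysis only if its methylation side has a SNP at p < 1e-6 and
its expression side one at p < 1e-4 within the 2 Mb window; by default the
filters gate eligibility only and all intersected SNPs enter the posterior
sums (a `restrict` mode keeps only filter-passing SNPs). Colocalization is
called at PP4 ≥ 0.80, boundary inclusive. Posteriors are validated against
exhaustive enumeration of every (causal-for-1, causal-for-2) assignment on
regions up to 10 SNPs.

## eQTM and trans-meQTL hotspots

eQTM scanning regresses expression residuals on methylation residuals for
all pairs, Bonferroni-corrected at the realized scan size
`α/(n_cpg·n_gene)` — computed, not hard-coded, because printed thresholds
derived from rounded scan dimensions are not exactly reproducible. A pair
is cis when the CpG lies within 1 Mb of the gene's TSS. Residualization
uses fixed covariates plus top principal components in place of surrogate
variables (out of scope); the PC count is configurable.

A hotspot is an index SNP whose genome-wide-significant trans associations
cover ≥ 30 CpGs. SNPs within 1 Mb or in LD (r² ≥ 0.2) merge into one
hotspot — a construction choice; a study reporting hotspot counts must
collapse LD-sharing index SNPs somehow, and distance-or-LD is the natural
rule for dosage data. The index is the member with the most targets (ties:
lowest p, then position). Hotspots link to eGenes — genes with a
significant cis-eQTL among member SNPs and TSS within 1 Mb — and the
hotspot's targets are tested for hypergeometric enrichment among all
eGene-associated CpGs, the observable signature of cis-gene-mediated trans
regulation.

## Enrichment

Membership annotations: exact hypergeometric test, two-sided as the doubled
smaller tail (the field reports both enrichment and depletion), significant
only when the fold change passes the > 1.2 / < 0.8 gate at
Bonferroni-corrected p. Interval annotations (chromatin states): each of
n_perm permutations draws, per MAF bin — (0.01,0.05], (0.05,0.1],
(0.1,0.2], (0.2,0.5], left-open right-closed — exactly the tested set's
count from the pool; fold = observed overlap / mean permuted overlap;
empirical add-one p `(1+#{perm ≥ obs})/(n_perm+1)` (mirrored for
depletion), Benjamini–Hochberg FDR across states, significant at
FDR < 0.05. SNP points overlap half-open BED intervals. The two modes are
cross-validated against each other on a MAF-neutral fixture at 1e5
permutations.

## The synthetic cohort

The generator produces what the downstream stages need to be tested, with
truth recorded per draw:

* **Pedigrees**: nuclear families (configurable parent count and sibship
  range) plus singletons; K and H as above.
* **Genotypes**: founder haplotypes from a first-order Markov chain whose
  adjacent-SNP allele correlation is calibrated to `√(adjacent_ld_r2)`
  (dosage r² then matches `adjacent_ld_r2`; long-range LD decays
  geometrically). Allele frequencies follow a reflected random walk inside
  `maf_range` so adjacent frequencies are similar — as in real LD blocks —
  and the target correlation is attainable; per-pair correlation is capped
  at the maximum compatible with the marginals, keeping conditional
  probabilities unclipped and marginal frequencies exact. Offspring receive
  recombined parental haplotypes (per-gap recombination probability
  `1−exp(−ρ·gap)`, default ρ = 1e-8/bp). Calibration check: target 0.6
  gives mean adjacent r² 0.600 at n = 2000.
* **Methylation**: latent trait `z = Σ β_k g_k + a + c + e`, components
  standardized empirically so realized variance fractions equal the
  configured (cis r², h², household) exactly in the generator's algebra;
  `a` is drawn via a Cholesky factor of K (+1e-8 ridge), `c` via H. Cis
  effects split `cis_effect_r2` equally over up to `n_cis_snps_per_cpg`
  mutually low-LD SNPs within 1 Mb (default 3 — one causal variant cannot
  furnish three independent MR instruments). Beta values are
  `0.02 + 0.96·logistic(0.25·z)`: the gentle slope keeps the map nearly
  linear over the bulk of the latent distribution, so variance fractions
  survive the squash (REML recovery at h² = 0.6 is unbiased to within
  Monte-Carlo error); the realized latent→beta slope is recorded per CpG.
* **Hotspots**: a mediating gene's expression is driven by the hotspot SNP
  (`hotspot_gene_r2`, default 0.5) and remote target CpGs by the mediator
  (`mediation_r2`), so hotspot detection, eGene linkage and the
  regress-out-the-mediator attenuation signature are all consequences of
  the generative mechanism rather than assertions.
* **Expression**: coloc-paired genes share (H4) or do not share (H3,
  partner r² < 0.05) the CpG's causal variant; other genes are noise.
* **Outcome GWAS**: per instrument, `Γ_j = θ·γ_j + α_j + ε_j` where γ_j is
  the true SNP→methylation effect on the measured beta-value scale (latent
  effect × recorded squash slope), α_j directional pleiotropy
  (mean `pleiotropy_mean`), and ε_j has the standard error implied by
  `gwas_n` and allele frequency under a standardized trait
  (`se = (2·maf·(1−maf)·n)^(−1/2)`). A configurable fraction of rows is
  emitted with swapped alleles and negated beta so harmonization is
  exercised. θ is the causal effect per unit methylation beta value.

All stages draw from independent streams spawned from the single config
seed; identical configs give byte-identical outputs.

**What the synthetic validation does not show.** The generator has no
batch or chip artifacts, no cell-type composition, no measurement-error
heteroscedasticity across the beta range, Markov LD rather than coalescent
haplotype structure, and uniform recombination. Passing tests demonstrate
that the estimators recover their own generative models at realistic
effect sizes and sample sizes — not that real-data preprocessing
(normalization, cell-fraction adjustment, surrogate variables, all out of
scope) is handled.

## Problem sizes used in validation

Heritability recovery: 250 sib-quad families (n = 1000), 20 replicates per
h² level. Scan oracle equivalence: 1e4 pairs at n = 400. Power and null
calibration: 1e5-pair scans at n = 1000 (power) and n = 500 (null, 20
runs). MR: 1000 null CpGs, 100 recovery and 100 outlier replicates, 200
Egger replicates, at summary level with 5–10 instruments. Colocalization:
100-SNP regions at n = 2000, 50 replicates per arm. Hotspots: 40 planted
targets among 55 CpGs and 120 SNPs at n = 800, 50 replicates. Enrichment:
500 test / 5000 pool SNPs, 200–1e5 permutations. These sizes put
Monte-Carlo error comfortably inside each test's acceptance band while the
full suite stays fast enough to run routinely.

## Known limitations

* Single-causal-variant colocalization only; no conditional or SuSiE-style
  multi-signal analysis.
* MR omits weighted-median/mode estimators, MR-PRESSO, Steiger filtering
  and bidirectional analysis.
* REML fits univariate models only (no genetic correlations, dominance or
  epistasis).
* The hotspot merge rule (1 Mb or r² ≥ 0.2) is a construction of this
  package; different collapsing rules change hotspot counts on real data.
* Permutation enrichment assumes the pool excludes the tested SNPs and is
  large enough per MAF bin; it errors otherwise rather than resampling.
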
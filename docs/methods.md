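# Methods

`reqtl` detects *response eQTLs*: genetic variants whose effect on a
gene's expression depends on a treatment condition, measured in paired
aliquots of the same cell line (one treated, one vehicle control).  The
motivating application is the transcriptional response of
lymphoblastoid cell lines to glucocorticoid (dexamethasone) treatment,
but nothing in the machinery is specific to that system: any paired
two-condition phenotype with per-individual genotypes fits.

## The five interaction models

For one gene and one SNP with minor-allele dosage `x ∈ {0,1,2}`, each
individual contributes a pair `(y_T, y_C)` of log2 expression values.
Five models describe the per-condition additive genotype effects
`(β_T, β_C)`:

| model | constraint            | interpretation                       |
|-------|-----------------------|--------------------------------------|
| M0    | β_T = β_C = 0         | no association in either condition   |
| M1    | β_T = β_C             | same effect in both (no interaction) |
| M2    | β_C = 0               | effect only under treatment          |
| M3    | β_T = 0               | effect only in control               |
| M4    | β_T, β_C free         | different effects (general)          |

M2–M4 are the interaction models; a gene classified M2–M4 has a
response eQTL.

## Likelihood: the difference/average decomposition

The two measurements of one individual share an individual-level
component `u` (culture batch, EBV load, growth state …), which induces
the pairing correlation `σ_u²/(σ_u²+σ_e²)`.  Transforming to

    d = y_T − y_C        (log fold change)
    m = (y_T + y_C)/2    (per-individual average)

cancels `u` in `d` and loads it entirely on `m`, so under equal
per-condition residual variances the two blocks are independent
Gaussian regressions with their own precisions `τ_d`, `τ_m`.  Effects
map linearly: `β_d = β_T − β_C`, `β_m = (β_T + β_C)/2`.  Per-condition
quantile normalization makes the equal-variance assumption mild.

Residual precisions are plugged in from the residuals of each block on
`[1, x]` (denominator n−2), shared across all five models.  This keeps
every Bayes factor closed-form: with `V = 1/(τ·Σx²)` and
`z = β̂/√V`,

    BF = sqrt(V/(V+W)) · exp(z²W / (2(V+W)))

for one coefficient with prior variance `W` — the standard approximate
single-coefficient Bayes factor.  M1 involves only the `m` block (the
`d` block cancels in the ratio); M2/M3 are a single scalar effect
loading on both blocks with loadings (+1, +1/2) and (−1, +1/2),
combined by precision weighting; M4 factorizes exactly into the product
of a `d`-block BF (prior `2w`) and an `m`-block BF (prior `w/2`),
because independent `β_T, β_C ~ N(0, w)` induce independent
`β_d ~ N(0, 2w)` and `β_m ~ N(0, w/2)`.

`reqtl.quadrature` re-derives every BF by adaptive numerical
integration (nested 2-D for M4) and is used in the tests as the
independent oracle; agreement is at machine precision.

## Effect-size prior and its grid

The per-condition effect prior is `β ~ N(0, (σ_b·sd_y)²)` with `sd_y`
the pooled sd of the gene's treated and control values, making all BFs
invariant under affine transforms of the phenotype.  `σ_b` runs over a
grid whose weights are estimated hierarchically (below).

The default grid is `{0.8, 1.6}`.  The grid is deliberately restricted
to effect scales detectable at panel sizes near 100: the sampling sd of
a genotype slope at n≈114 and intermediate MAF is ≈0.2·sd_y, and a
mixture component whose prior sd sits at or below that scale is
statistically indistinguishable from the null.  Including such
components makes the genome-wide model proportions unidentifiable — the
EM can reallocate null genes to "negligible-effect association"
components almost without likelihood cost, and measured recovery errors
on simulated data reach 0.3–0.6 on π.  With the restricted grid the
same simulations recover every proportion to within ~0.02.  The cost is
explicit and documented: π estimates count *detectable* associations;
genes with sub-threshold effects are absorbed into π0, as in any
detection-limited mixture estimate.  Functions accept arbitrary grids
for sensitivity analyses.

## Hierarchical model, EM, posteriors, FDR

Within a gene's cis window (gene body ±100 kb by default, strand
ignored) at most one eQTL is assumed, with a uniform prior across the
S window SNPs, so the gene-level BF is the arithmetic mean of SNP BFs.
Genome-wide, gene `g` follows model `M` with probability `π_M`; the EM
estimates these proportions — and, in the pipeline default
(`em_fit_grid`), the conditional grid weights per model — by maximizing
`Σ_g log Σ_{M,j} w_{Mj} GBF_g(M, σ_j)`.  The log-likelihood is
non-decreasing per iteration (asserted in tests); components hitting
zero are floored at 1e−8 and renormalized.  `em_fit` (fixed uniform
grid weights, genes × 5 models) is retained as the simpler surface.

Per-gene posteriors are `PP_g(M) ∝ π_M·GBF_g(M)`; the interaction
posterior is `PP(M2)+PP(M3)+PP(M4)`; `best_model` is the argmax over
M1–M4 (ties to the lower model index).  The Bayesian FDR among genes
selected at `PP > t` is the mean of `1 − PP` over the selection — on
data simulated from the model it tracks the realized false-discovery
proportion to within ~0.01 (measured by the acceptance script).  The
eQTN is the SNP maximizing the prior-weighted mixture of its BFs, ties
to the smallest position.  A SNP-level interaction BF contrasts
M2–M4 against M0–M1 with the fitted priors renormalized within each
group.

## Frequentist comparator and permutation FDR

The log-fold-change scan regresses `d` on dosage per SNP (plain OLS,
two-sided t), takes the per-gene minimum p over the window, and builds
the null by permuting genotype labels against the paired phenotype
rows.  One reordering per round is shared by all genes, preserving the
cross-gene correlation structure of the null.  The FDR at threshold `t`
is

    FDR(t) = [(1 + #{perm p ≤ t}) / R] / max(1, #{obs p ≤ t})

clipped to [0,1] and made non-decreasing in `t`.  The add-one
pseudocount keeps the estimate away from an exact zero when the top
observed p beats every permutation value — without it, a global-null
scan of 1000 genes declares at least one "FDR 0" gene in ≈1/(R+1) of
replicates no matter how many rounds are run; with it, 100/100 null
replicates are clean at FDR<0.1 (measured).  `pseudocount=0` gives the
plain ratio.  Default round counts: 100 for cis windows, 10 for
differential expression and 500-kb candidate scans, 3 genome-wide; all
configurable.  p-values are floored at 1e−300.

Differential expression on treatment is a per-gene OLS of pooled
quantile-normalized expression on `[1, treatment, covariates]` with the
same permutation FDR applied to label permutations.

## Population contrast

A 0/1 population label is statistically a haploid dosage, so the same
engine tests population×treatment interactions: per gene, treated and
control vectors are quantile-normalized across individuals (per
condition), BFs are computed with the population indicator as
predictor, and a separate EM is fit over genes.  Response direction is
the sign of the mean log fold change; the "stronger" population is the
one whose mean response is larger in that direction.  Predicted
between-population response differences at eQTNs are
`2·β̂·(f₁ − f₂)` — per-copy effect times the expected dosage difference
under Hardy–Weinberg — and are regressed (with intercept) on observed
mean differences to give r² and p.  Enrichment of interaction eQTLs
among population-different genes uses the cross-product odds ratio
(Haldane 0.5 correction only when a cell is zero) with a two-sided
Fisher exact p.

## Validation statistics

Allelic imbalance: within one treatment, natural-log allelic ratios
(numerator fixed to the allele associated with increased expression)
are quantile-normalized and heterozygotes are compared to homozygotes —
which carry no true imbalance — by a one-tailed Welch t-test
(heterozygote mean greater).  Welch rather than pooled variance is a
deliberate choice; group sizes and variances from qPCR assays are
rarely balanced.  Set overlaps are scored by the upper-tail
hypergeometric probability.

## The simulator

`reqtl.simulate` is the generative inverse of the analysis likelihood:

    y_C = β_C·x + u + ε_C
    y_T = Δ_g + β_T·x + u + ε_T

with `u ~ N(0, σ_u²)`, `ε ~ N(0, σ_e²)`, per-gene treatment shift
`Δ_g ~ N(0, 0.5²)`, and optional linear covariate effects added to both
conditions.  Genotypes are Hardy–Weinberg draws from per-population MAF
ranges (default U[0.05, 0.5) in both populations); non-causal window
SNPs copy each causal allele with probability `ρ_LD` (default 0.5) and
redraw otherwise — enough LD structure to exercise SNP averaging
without a coalescent.  The causal SNP sits at the window center.

Default study shape: 57 + 57 individuals in two populations, 500 genes
(2000 in the acceptance runs), 10 SNPs per window,
π = (0.70, 0.20, 0.05, 0.03, 0.02), effect scale β = 0.8 in units of
`sd_y = sqrt(σ_u² + σ_e²)`, σ_u² = σ_e² = 1 (pairing correlation 0.5).

Per-gene effects are drawn, by default, from the model's own effect
prior `N(0, (β·sd_y)²)` (`effect_distribution="normal"`), with M4
drawing the two condition effects independently.  This choice matters:
with fixed-magnitude effects (`"fixed"`, ±β·sd_y) the mixture MLE of π
is inconsistent even under a matched point prior (a known-variance toy
puts π̂1 at 0.31 for a true 0.20), because the fitted component
densities integrate over a spread of effect sizes the generator never
produces.  Fixed-magnitude draws remain available and are used where a
definite per-gene effect is the point — slope moment checks and the
classification-rate measurements.

What the simulator does *not* emulate: microarray probe effects and
background, realistic haplotype/recombination structure, expression
outliers and heavy tails, trans effects, multiple eQTLs per gene, and
ancestry structure beyond the two-label design.  Passing tests
therefore demonstrate correctness of the machinery under its own
assumptions and honest calibration against model-matched data — not
robustness to every failure mode of real microarray data.

## Problem sizes and numerics

Acceptance-scale runs use 2000 genes × 10 SNPs × 114 individuals
(seconds for the Bayesian pipeline) and 100 replicates of 1000 null
genes for permutation calibration; the quadrature oracle covers 100
instances at n=30 across a six-point grid spanning σ_b 0.05–1.6.  EM
tolerance is 1e−6 on the log-likelihood with a 10,000-iteration cap and
null-heavy initialization (0.9, 0.04, 0.02, 0.02, 0.02).  SNPs are
skipped (with a recorded reason) when complete cases < 5, the dosage is
constant, the minor-allele count among used individuals is < 2, or a
block has zero residual variance.  All positions are internally
0-based; BED input is taken as-is and VCF positions are shifted by one.
Minor-allele orientation is computed over non-missing individuals with
ties at frequency 0.5 keeping the alt allele.

## Known limitations

* One eQTL per gene; genes carrying both interacting and
  non-interacting variants will have interaction probabilities
  underestimated.
* Plug-in block precisions ignore the uncertainty of the variance
  estimates; at n ≈ 100 the effect is negligible for calibration but
  BFs are approximate, not exact marginal-likelihood ratios.
* The π estimates are detection-limited (see the grid discussion).
* No kinship or ancestry adjustment; individuals are assumed unrelated
  and populations are taken as given labels.
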
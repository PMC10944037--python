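# Methods

This note documents the models, numerical choices and limitations behind
`proteomr`. It covers the five analysis stages and the synthetic-data
generator that stands in for the cohort, pQTL and GWAS resources.

## Survival screen

Protein abundances (positive, fluorescence-unit-like) are natural-log
transformed and z-scored per protein over non-missing subjects, so every
hazard ratio is per 1 SD of log abundance. Log transformation is the
package's choice: abundance distributions from affinity assays are
right-skewed and multiplicative, and the transform makes "per SD" effects
comparable across proteins. Non-positive readings are treated as missing;
proteins with zero variance or fewer than three values are excluded with a
recorded reason.

Each protein is fit in its own Cox proportional-hazards model (Efron tie
handling, Newton–Raphson; fits delegate to `lifelines.CoxPHFitter`),
unadjusted or adjusted for a composite clinical risk score plus log
natriuretic peptide, complete-case per protein. Fewer than two events is
an unidentifiable model and raises; per-protein convergence failures are
logged and skipped, never fatal. The test suite checks the fit against a
brute-force one-dimensional grid search over the Breslow partial
likelihood on tie-free data (where Efron and Breslow coincide).

Multiple comparisons use the effective number of tests: the smallest
number of principal components of the protein–protein correlation matrix
explaining at least `variance_threshold` (default 0.95) of total variance;
the corrected alpha is 0.05 divided by that count. The default threshold
is a conventional choice for this style of correction; the count is exact
on degenerate inputs (identical proteins give 1, two perfectly correlated
blocks give 2).

## Summary-statistic harmonization

Positions are 1-based inclusive; BED-like locus tables are converted on
read. Only A/C/G/T single-nucleotide variants are retained (indels and
multi-allelic rows are dropped with a reason). Outcome effects are aligned
to the exposure's effect allele: direct label match, then swap (beta sign
flips), then a strand flip (A<->T, C<->G) before declaring a mismatch.
Palindromic variants carry no strand information in their labels; they are
kept only when both studies' effect-allele frequencies fall on the same
side of 0.5 and outside 0.5 ± 0.08 (a standard band in two-sample MR
practice; the choice is the module's own, as is the whole harmonization
convention — how the original exposure and outcome resources were aligned
is not recoverable from summary data). Every drop carries a reason in the
audit table, and harmonization is idempotent.

LD matrices are signed with respect to each variant's effect allele;
flipping an allele flips the corresponding row and column. Matrices are
repaired to positive semidefinite by `(R + eps I)/(1 + eps)` with
`eps = |lambda_min| + 1e-8` applied only when the smallest eigenvalue is
negative, which preserves the unit diagonal and touches exactly-singular
matrices (duplicated variants) not at all.

## Collider-bias correction

Model: among variants that pass an incidence p-value filter (default
p < 1e-3; at least 30 required), the pairs (b_inc, b_out) follow a
two-component mixture — an "incidence-only" component on the line
`b_out = slope * b_inc` with excess dispersion `s1^2` plus the known
per-variant sampling noise `se_out^2`, and an unconstrained independent
bivariate normal for variants with genuine outcome effects. The EM
algorithm runs 10 restarts from perturbed initialisations on a fixed seed
schedule and keeps the best likelihood; anchoring the residual variance at
the known sampling noise keeps the line component from tilting to absorb
well-measured points. A one-component (everything-on-the-line) fit is also
computed and selected by BIC when the data show no second cluster — the
mixture is unidentified on such data and can otherwise lock onto a small
tilted subset. The slope SE is a sandwich estimate over the final
responsibility-weighted regression, robust to the soft assignment.

Adjustment: `b_adj = b_out - slope * b_inc` for every variant with
incidence data; `se_adj^2 = se_out^2 + slope^2 se_inc^2 +
b_inc^2 se_slope^2`; p-values are recomputed under a normal
approximation. Variants without incidence data pass through unchanged and
are flagged. Because the slope estimate is shared, its error correlates
the adjusted effects of different variants;
`adjusted_outcome_covariance()` returns the full covariance (diagonal plus
the rank-one `se_slope^2 b_inc b_inc'` term) for analyses that combine
several adjusted variants. The pipeline's per-protein IVW uses the
diagonal propagation plus the LD matrix; at the slope precisions produced
by a consortium-scale incidence GWAS the rank-one term is negligible
there, and the calibration experiments use the full covariance.

## Instruments and MR

Candidates are cis (gene body ± 500 kb, inclusive bounds, same chromosome)
or trans (everything else), retained iff p < 5e-8 strictly; trans
candidates in the extended MHC (chr6:25–34 Mb) are excluded because its
LD and pleiotropy make trans signals unreliable. Greedy p-value clumping
at r² < 0.1 is a light pre-filter for numerical stability of the GLS
inverse — residual correlation is deliberately retained and modelled.
Instrument strength is summarised by the mean F statistic,
`mean((b_X/s_X)^2)`; sets at or below 10 are flagged weak.

Estimators: correlated-instrument fixed-effect IVW (generalised least
squares with `Omega = diag(s_Y) R diag(s_Y)`; equals textbook
fixed-effect IVW at R = I and the Wald ratio for one instrument),
Cochran's Q against the fitted slope as the heterogeneity diagnostic,
MR-Egger (weighted regression with intercept, instruments oriented so all
b_X >= 0), and the weighted median (interpolated crossing of cumulative
inverse-variance weight at 0.5, SE by seeded parametric bootstrap,
1000 resamples by default, 500 in the pipeline). Wald SEs are first-order
(`s_Y/|b_X|`) with a second-order option. P-values are two-sided normal.
Fixed-effect rather than random-effect IVW is the package's choice, with
Q reported so heterogeneity is visible. Allele-flip equivariance holds in
the joint sense: negating an instrument's b_X and b_Y together with its
LD row/column signs leaves theta unchanged; negating all b_Y negates
theta.

## Colocalization

Per-variant approximate Bayes factors from (beta, se) with prior effect
SD W: `log ABF = 0.5 log(1-r) + 0.5 r z^2`, `r = W^2/(W^2 + se^2)`.
Defaults W = 0.15 for the quantitative trait (protein, SD units) and
W = 0.2 for the case-control trait (log-odds), conventional values for
this family of methods. Single causal variant per trait per region; the
hypothesis weights are prior-scaled log-sum-exp sums of ABFs, with the
distinct-variant (H3) sum computed as an exact pairwise log-sum-exp over
off-diagonal pairs for regions up to 2000 variants (the subtraction
shortcut loses ~1e-9 of log precision to cancellation; beyond 2000
variants it is used as a memory fallback). Priors: p1 = p2 = 1e-4 per
SNP per trait; p12 = 1e-5 with a mandatory sensitivity grid, since the
shared-causal prior is the least constrained input — results are flagged
prior-sensitive when the colocalization call (PP_H4 > 0.8) flips across
the grid. Conditional colocalization is `PP_H4/(PP_H3 + PP_H4)`, missing
when the denominator is zero. The region is the cis window by default
(configurable); posteriors are invariant to variant order and are checked
against exhaustive enumeration of all causal-configuration pairs.

## Synthetic data

The generator emulates every data role with a known truth file:

* **Genotypes.** Latent-Gaussian AR(1) LD within each cis region
  (`corr = ld_decay^|i-j|` between alleles after arcsine-law compensation
  of the dichotomisation attenuation), two haplotypes thresholded at the
  MAF quantile; region MAFs share an anchor frequency as in real LD
  blocks. Background liability variants are independent, standing for
  genome-wide clumped incidence hits, with effect magnitudes bounded away
  from zero (they represent loci that were themselves discovered at
  genome-wide significance).
* **pQTL study.** Proteins are cis genetic scores rescaled to a target
  heritability plus noise; marginal per-variant regressions in an
  independent sample are emitted as summary statistics.
* **Disease population.** Liability = background genetic score + protein
  effects + shared frailty u + noise; subjects above the
  `1 - case_fraction` quantile become cases. Conditioning on liability
  makes genotypes anti-correlated with u among cases while u drives both
  outcomes — collider bias by construction, with the induced slope
  recorded implicitly through the truth parameters.
* **Cohort.** Exponential survival times for death and HF admission with
  log-hazard = causal protein effects + frailty; one administrative
  censoring window; baseline rates solved by bisection so that death and
  the composite endpoint hit their target rates (≈26% and ≈52%,
  competing-process arithmetic included). Clinical covariates (risk
  score, log natriuretic peptide) are noisy proxies of the frailty
  factor, so adjustment attenuates confounded associations. Binary-trait
  GWAS effects are emitted on the log-odds scale via the
  linear-probability rescaling `beta / (p(1-p))`.

Default scales: 2,000-subject proteomics cohort within a 12,000-person
population at 25% case fraction, 15,000-sample pQTL study, 2,000-sample
LD reference panel, 20 proteins × 30 cis variants, 80 background
variants. The reference scenario (`demo_config`) gives one protein a
causal effect of log-odds 0.7 per SD (OR ≈ 2, the scale of the largest
replicated protein effects on HF outcomes) through a strong cis locus
(h² = 0.2) and makes six proteins confounded with the frailty factor.
All randomness flows from one `numpy.random.default_rng` (PCG64) seeded
by the config, so a config maps to exactly one dataset.

The reduced collider replicate used in calibration experiments pairs a
summary-level exposure study with individual-level outcome and incidence
GWAS (8,000-person progression population, 30,000-person incidence study,
100 background hits, 5 instruments, protein liability effect 0.4 SD per
SD).

What the generator does *not* emulate: assay batch effects and aptamer
cross-reactivity, population structure and relatedness, imputation error,
multi-ancestry LD, time-varying hazards, and competing-risk informative
censoring. Passing tests therefore demonstrate the statistical machinery
under a clean generative model, not robustness to those artefacts.

## Pipeline and gating

Only proteins passing the corrected screening alpha advance to MR; only
proteins with IVW p < 0.05 (nominal, justified by the prior screening
filter) in at least one exposure source advance to colocalization. The
top evidence tier `MR+coloc-supported` requires conditional PP > 0.9 —
the conditional probability is used for the tier (rather than the raw
PP_H4 > 0.8 signal flag, which is also reported) because outcome GWAS of
modest size can hold strong mechanistic evidence of sharing while PP_H4
is deflated by H0/H1 mass. When several exposure sources are supplied,
per-source results are reported with a `replicated` flag instead of a
pooled estimate. A manifest records the configuration and per-stage
counts; reruns with the same config and seed are byte-identical.

## Problem sizes in tests and the acceptance script

Simulation-based checks use: 500 replicates for collider-bias removal
and MR effect recovery, 2,000 for MR null calibration, 200 for Cox
recovery at n = 2000, 50 seeds each for slope recovery (5,000 variants)
and the end-to-end scenario (20 proteins). The acceptance script reports
the same quantities at 200/30/10 replicates or seeds where the full count
would add nothing but runtime; each JSON entry records the size used.

## Known limitations

* The Cox screen offers no proportional-hazards diagnostics, competing
  risks or time-varying covariates.
* Collider correction assumes the induced incidence–outcome relation is
  linear with no interactions; variants with very large liability effects
  deviate at second order, leaving a small residual after adjustment.
* Single-causal-variant colocalization: no conditioning or masking for
  secondary signals.
* MR sensitivity is limited to Egger, weighted median, Cochran's Q and
  the F statistic — no MR-PRESSO, Steiger filtering or multivariable MR.
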
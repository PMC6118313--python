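# Methods

## The model

`medlmm` partitions the effect of a focal biallelic variant `x` on a
quantitative phenotype `y` into a component transmitted through a mediating
gene-expression level `m` and a residual direct component, while modelling
the confounding polygenic background of a structured panel of inbred lines
as a kinship random effect. The two estimating equations are

    m = x b1 + u1 + eM,   u1 ~ N(0, s1^2 K),  eM ~ N(0, sM^2 I)
    y = x b2 + m t1 + u2 + eY,   u2 ~ N(0, s2^2 K),  eY ~ N(0, sY^2 I)

with `K` the identity-by-state (IBS) kinship over the genotyped SNPs and
per-equation background-to-noise ratios `lambda1 = s1^2/sM^2`,
`lambda2 = s2^2/sY^2` estimated by REML. In this no-interaction linear
model the counterfactual natural direct and indirect effects reduce to
closed forms: per unit exposure contrast,

    NDE = b2,    NIE = b1 * t1,    total = b2 + b1 * t1,

and the proportion mediated is `NIE / (NDE + NIE)`. When NDE and NIE have
opposite signs the ratio falls outside [0, 1]; it is then reported with an
"inconsistent mediation" flag rather than clamped. The controlled direct
effect coincides with the NDE here, so no separate quantity is reported.

Phenotype, mediator and genotype are each standardized to mean 0 and
population (divisor-n) unit variance before fitting, so effects are on a
common scale and the proportion mediated is scale-free. Raw-scale fitting
is available (`standardize_inputs=False`).

### Assumptions

- Lines are fully homozygous (one 0/1 call per line); heterozygous VCF
  calls are treated as missing and imputed to the column major allele.
- No exposure-mediator interaction; the mediator precedes the phenotype
  causally (expression measured well before the phenotype manifests).
- The two equations' random effects are drawn independently; correlated
  backgrounds are exactly the confounding scenario the kinship term is
  there to absorb, and the synthetic generator can produce them (below).

## Estimation

A single spectral decomposition `K = U S U'` is shared by both equations.
After rotating by `U'` the covariance is diagonal, so the profiled REML
(or ML) likelihood of the variance ratio costs O(nq) per candidate. The
ratio is maximized on a 100-point log grid over [1e-5, 1e5], refined by
bounded scalar optimization; ties — the profile is exactly flat when
`K = I` — are broken toward the smaller ratio, and boundary solutions are
reported with a warning rather than an error. Fixed effects are the GLS
estimates at the optimum with covariance-based standard errors; Wald tests
use a t reference with `n - q` degrees of freedom (conservative at small
n; a normal reference is available).

Association scans reuse the null-model ratio for every SNP (the standard
population-parameters-previously-determined approximation); the per-SNP
2-covariate GLS is closed-form and vectorized across the genome. The
uncorrected comparator (`mode="LM"`) sets the ratio to zero. Scan
calibration is summarized by the genomic inflation factor, the median
observed chi-square(1) quantile over its theoretical median 0.4549.

## Permutation tests

The indirect effect is tested against the null `b1 = 0` by permuting the
mediator across lines `n_perm` times (default 1500) while phenotype,
genotype and kinship stay fixed; only the mediator equation is refit (the
null kills the indirect path through `b1` alone), with the variance ratio
re-estimated each time on a coarse grid plus two vectorized zoom rounds
(within ~1% of the fine-grid optimum). `p = (1 + #{perm >= obs}) /
(n_perm + 1)` with statistic `|b1_hat|`.

Under exchangeable nulls the test is exact; measured type-I error at
nominal 0.05 is 0.040 (500 datasets). When the mediator itself carries
kinship structure the permutation destroys that structure and the test
becomes mildly conservative (~0.027 measured on structured panels) —
conservative, never anti-conservative, which is the safe direction for a
discovery screen.

## Variance components (cis/trans)

Expression traits are decomposed as `y = mu + u_local + u_global + eps`
with IBS kinships over the SNPs within a window around the gene (default
flank 15 kb, closed 1-based intervals) and over the whole genome. Two
kinships cannot be jointly diagonalized, so the restricted likelihood is
evaluated by Cholesky factorization and maximized by Nelder-Mead over log
variance ratios (4 restarts; non-negativity by construction). Both
matrices are Gower-scaled by default — scaled so the centered trace equals
`n - 1` — because raw IBS matrices share a large constant allele-sharing
baseline that makes component variances incommensurate with trait
variance; with the scaling, component sums track `var(y)` and fractions
are on the variance-explained scale. Identical local and global matrices
are flagged as non-identifiable (`degenerate=True`) with a boundary
solution reported. Significance of `frac_local` comes from jointly
permuting the trait's line labels against both kinships (preserves the
relatedness structure, breaks the trait-genotype link); the scheme used by
the original local-vs-global implementations is not published in detail,
so this documented choice stands in for it.

## Explained variance and prediction transfer

The marginal r^2 of an LMM is the realized variance of its fixed-effect
linear predictor over the total of fixed, kinship-attached and residual
variance. The kinship term counts only the centered structure of K
(`sigma_g^2 tr(PKP)/(n-1)`, P the centering projector): the constant
baseline of an IBS matrix is absorbed by the intercept and contributes
nothing across lines. All variances use the divisor-n convention, making
the no-kinship limit coincide exactly with the ordinary coefficient of
determination. The partition reports `r2_total` (SNP + mediator model),
`r2_snp` (SNP-only model) and `r2_expression = r2_total - r2_snp` — the
subtraction is the operative definition; the direct mediator-only fit is
available for comparison but can disagree because the mediator and SNP
share variance. A negative subtraction result is flagged, not clamped.

Prediction transfers `(b2, t1)` from a fitted panel to a new one under
the assumption that background effects on mediator and phenotype are
proportional: the new panel's background is the BLUP of the random effect
from an intercept-only REML fit of the new mediator, and
`y_hat = b2 x_new + t1 m_new + background`. Two accuracy measures are
reported: `r2_pred`, the squared correlation of `y_hat` with the observed
phenotype (includes background-tracking skill), and `r2_model`, the
variance of the transferred fixed-effect predictor over the observed
phenotypic variance — the same marginal-r^2 scale as training, hence the
measure used when comparing transfer against the training `r2_total`.
Whether the new panel carries any kinship-attached mediator variance is
tested by permuting the mediator against the kinship and re-fitting the
null model (one-sided p on the variance fraction).

## Synthetic data

The generator exists so every stage is testable with known ground truth:

- **Genotypes**: Balding-Nichols two-level allele frequencies (ancestral
  ~ U(0.1, 0.9), population frequencies Beta-perturbed with the divergence
  parameter playing the role of F_ST), haploid-equivalent 0/1 calls,
  positions on 5 synthetic 30-Mb chromosomes. Defaults n = 300 lines, 2
  equal subpopulations, divergence 0.3 — enough structure that uncorrected
  scans visibly inflate. Near-monomorphic columns are redrawn so every SNP
  is usable.
- **Mediator/phenotype**: exactly the two-equation model, with background
  effect vectors drawn per SNP (variance `s_i^2/p`) over the standardized
  non-focal SNPs, optionally correlated across equations (`rho_gamma`,
  default 0.5) — the knob that produces genuine mediator-outcome
  confounding. Noise variances are solved so `m` and `y` have unit
  expected variance; the stated effects (defaults b1 = 0.4, b2 = 0.25,
  t1 = 0.51, lambdas = 1) are then already on the standardized scale the
  fitting stages use and estimates are directly comparable with the truth.
- **Expression panels**: per gene a mixture of a local-window genotype
  score (planted cis fraction), clique-shared latent factors (planted
  correlation backbone), optional trans-hub routing, and noise.

What the generator does not emulate: linkage disequilibrium beyond shared
population structure, selection, vernalization or any environmental
response, mediator measurement error correlated with the phenotype, and
count-like expression noise. Passing tests therefore demonstrate correct
inference under the model's own assumptions and under kinship-style
confounding — not robustness to every feature of real transcriptomes.

Two scale caveats measured during development: fitted variance ratios are
on the scale of the kinship supplied — with IBS kinship they carry an
allele-frequency-dependent factor (~2.4x in our conditions) relative to
the realized-relationship matrix `ZZ'/p`, under which they are recovered
essentially exactly; fixed effects are unaffected. And with correlated
backgrounds (`rho_gamma > 0`) the mediator covaries with the outcome
equation's random effect, which inflates `t1` for any kinship — a
property of the estimand, visible in the generator, corrected neither by
LM nor LMM (though LMM reduces the bias in the direct effect).

## Numerical choices

- Lambda grid [1e-5, 1e5], 100 points, bounded refinement; permutation
  path uses 41 points plus two 9-point zooms.
- Kinship PSD repair: +1e-8 I when the smallest eigenvalue is negative
  (possible after mean imputation); eigenvalues clipped at 0.
- SNPs with more than 10% missing calls are dropped; the rest mean-imputed
  before kinship construction.
- MAF filtering excludes `MAF <= threshold` (strict retention).
- Two-component optimizer: log-ratio bounds [-18, 9], Nelder-Mead xatol
  1e-4, 4 restarts (2 inside permutation loops).
- Spearman p-values: exact permutation enumeration below n = 10,
  t-approximation with average-rank ties otherwise.
- Proportion mediated undefined (NaN + flag) when |total| < 1e-8.

## Problem sizes in the test suite

Statistical checks run at n = 300 lines with 500-5000 SNPs and 10-100
seeds per claim (the sizes quoted in each test's docstring); permutation
calibration uses 500 exchangeable null datasets at n = 150 with 99
permutations, and the variance-component permutation calibration uses
n = 100 panels. These sizes were chosen so each claim's Monte-Carlo error
is small relative to its tolerance while the whole suite stays fast
enough to run routinely.

## Known limitations

- One mediator at a time; no multi-mediator decomposition, interactions,
  or sensitivity analysis for unmeasured confounding.
- The EMMAX-style fixed-ratio scan approximation slightly misstates
  per-SNP variances when a SNP has a large effect (the exact per-SNP refit
  is available).
- Two variance components maximum; no general n-component solver.
- The indirect-effect permutation test is conservative when the mediator
  is strongly heritable (see above).
- IBS is the only kinship estimator provided; realized-relationship
  matrices can be supplied externally since all fitting functions accept
  arbitrary PSD kinships.
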
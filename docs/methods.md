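# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `famlod`, and what its simulation-based tests do and do not
demonstrate.

## Trait model and likelihood

Within family *f* with *n_f* phenotyped members, the (covariate-adjusted)
trait vector `y_f` is modeled as multivariate normal:

    y_f ~ N(mu * 1,  Omega_f),     Omega_f = vq * Pi_f + va * 2*Phi_f + ve * I

* `Pi_f` — pairwise proportions of alleles shared identical by descent at
  the tested locus (exact, from the simulator's inheritance labels);
* `Phi_f` — kinship coefficients from the standard tabular recursion on the
  validated, topologically sorted pedigree (handles inbreeding loops without
  special cases);
* `vq, va, ve >= 0` — locus (QTL), residual polygenic, and environmental
  variance components; `mu` is free in both models even though the analyzed
  trait is standardized (it guards against alternative adjustment schemes
  at negligible cost).

Families are independent, so the sample log-likelihood is the sum of family
terms. Each term is evaluated by Cholesky factorization; if the factorization
fails or the factor's diagonal indicates a condition number above 1e12, a
1e-8 diagonal jitter is added once (logged at debug level) before declaring
the matrix non-positive-definite, which is an error naming the family.

## Fitting, LOD, and the boundary

Maximum likelihood, not REML: the LOD score is a likelihood ratio, so both
models must be fitted by the same criterion. The optimizer is L-BFGS-B on
`(mu, log va, log ve[, log vq])` with analytic gradients
(`d l / d v_k = -1/2 [tr(Omega^-1 V_k) - r' Omega^-1 V_k Omega^-1 r]`,
chain-ruled onto the log scale). Three starts at fixed variance splits of
the pooled trait variance — (q, a, e) shares (0.1, 0.8, 0.1),
(0.3, 0.3, 0.4), (~0, 0.5, 0.5) for the full model — and the best
log-likelihood is kept; convergence tolerances are 1e-8 nats (ftol) and
1e-7 (projected gradient).

Because `vq = 0` lies on the boundary and is unreachable on the log scale,
the full-model fit always ends with an explicit **boundary probe**: the null
model's optimum (with `vq = 0`) is compared against the interior optimum and
kept if better. This guarantees `lnL_full >= lnL_null`, makes LOD = 0 exact
(not 1e-9) in boundary replicates, and is what produces the correct point
mass at zero in the null LOD distribution. LOD values in `[-1e-6, 0)` —
possible only through numerical noise — are clamped to 0; anything lower is
an error. The pipeline computes one null fit per (replicate, trait) and
reuses it across genes as each full fit's probe, since the null model does
not involve the locus.

**Family-specific LOD.** Family *f*'s score is its log-likelihood-ratio
contribution with *both* models evaluated at the whole-sample ML estimates:
`[l_f(theta_full) - l_f(theta_null)] / ln 10`. The per-family scores
therefore sum exactly to the total LOD (verified to ~1e-14 over random
datasets). The alternative convention — re-maximizing per family — was
rejected because the contributions would no longer add up and single-family
scores could exceed the total.

**Null distribution.** With one variance pinned at the boundary,
`2 ln(10) * LOD` is asymptotically the half-half mixture of chi-square(1)
and a point mass at 0, so `E[LOD] = 1/(4 ln 10) ~= 0.1086` and the p-value
of a LOD score is `0.5 * P(chi2_1 >= 2 ln 10 * LOD)` (0.5 at LOD = 0).
Monte-Carlo sampling of the mixture and the closed forms live next to the
fitting code; the package's own 500-simulation null calibration reproduces
the mixture (mean LOD, zero fraction ~1/2, KS on the positive part).

## Synthetic data generator

The generator emulates the GAW17 family simulation design so that every
stage runs without any external download. Defaults (all overridable through
`SimulationConfig` / YAML):

* **Pedigrees**: 8 extended pedigrees, 697 individuals, 202 founders
  (six of 87/25, one 87/26, one 88/26). Each is built deterministically:
  a founding couple, descendants marrying founder spouses in birth order,
  children distributed as evenly as possible across couples — giving 3-5
  generations. The originally analyzed pedigree structures are not public,
  so sizes and depths are configuration, not replication.
* **Variants**: founder allele copies are minor independently with
  probability MAF; *single-carrier mode* plants exactly one minor copy in a
  chosen founder (population MAF 1/(2N): 0.0717% for N = 697). A gene is
  treated as a point locus: all its variants share one gene-dropped
  inheritance vector, and exact IBD (`pi_hat = max-matching of the two
  allele-label pairs / 2`) is computed per gene per family. These matrices
  are provably positive semi-definite (the label-overlap count is a sum of
  `min` kernels).
* **Conditioning**: scenarios like "one founder copy reaching exactly 30
  descendant carriers" are reproduced by rejection sampling over seeded
  gene drops (default cap 1e5 tries; the default scenario needs ~400).
* **Phenotypes**: `y = mu + 0.01*age + 0.1*sex + 0.2*smoke + sum beta*c +
  g + e` with `g ~ N(0, 2*Phi*va)` per family and `e ~ N(0, ve)`;
  defaults `va = 0.3`, `ve = 0.5`, age ~ U(30, 75) years, smoking ~
  Bernoulli(0.3). Genotypes and covariates are fixed across the default 200
  replicates; only `g` and `e` are redrawn. The GAW17 covariate
  distributions and residual variances are not published; these defaults
  were chosen once to give a standardized-trait scale on which a strong
  single-carrier gene explains roughly a fifth to a quarter of its carrier
  family's phenotypic variance (beta = 1.0 with 31 carriers in an
  87-member family gives ~22%).
* **Determinism**: every stage's randomness derives from the master seed by
  a counter scheme (`SeedSequence(entropy=(seed, stage, gene, family))`),
  so identical config + seed give byte-identical outputs and any stage can
  be recomputed in isolation.

What the generator does **not** emulate: sequence-level data, linkage
disequilibrium between variants, marker-based (noisy) IBD estimation,
ascertainment, or non-normal trait distributions. Passing tests show the
method behaves correctly when its modeling assumptions hold exactly; they
do not measure robustness to LD, IBD estimation error, or trait
non-normality in real data.

## Covariate adjustment

Per replicate, pooled across families: OLS of the trait on intercept + age
+ sex + smoking, residuals divided by their sample SD (n-1). Relatedness is
deliberately ignored here — the residual familial correlation is exactly
what the variance-component stage models. Rank deficiency is detected by QR
and reported with the name of the first collinear column; a zero-variance
residual (trait determined by covariates) is an error. Adjustment is
idempotent.

## Enrichment evaluation

Per replicate the family with the largest family-specific LOD is selected;
ties go to the lexicographically smallest family id so runs are
reproducible. Per gene:

* **Expected** = (#families carrying >= 1 minor-allele copy of any of the
  gene's causal variants, transmitted or not) / #families;
* **Observed** = fraction of replicates whose selected family is a carrier;
* **p-value** = one-sided upper-tail one-sample proportion z-test without
  continuity correction, `z = (obs - exp) / sqrt(exp*(1-exp)/n)`. This test
  reproduces all published p-values of the GAW17 family evaluation from
  their (Expected, Observed, n = 200) triples to printed precision; an
  exact one-sided binomial alternative is available (`--test binomial`).
  Genes with Expected 0 (or 1) get an NA p-value; Expected-0 genes are
  flagged "null-hypothesis gene". No multiple-testing adjustment is
  applied.

**Known limitation (tie rule at the null boundary).** In a replicate where
the whole-sample `vq` estimate is exactly 0, all family-specific LODs are
exactly 0 and the deterministic tie rule returns the first family id. Under
a true null this happens in about half the replicates, so for a gene with
carriers but no effect the observed hit rate reflects the first family's
carrier status rather than random selection. The enrichment p-value is
therefore meaningful for genes with real signal (ties are then rare), and
the package flags no-carrier genes as null-hypothesis analyses, but
"zero-effect gene with carriers" scenarios should be interpreted with this
artifact in mind (a randomized tie-break would trade reproducibility for
calibration).

## Variance explained

Per gene, the additive score `sum_v beta_v c_v` is fixed across replicates;
the percent of variance explained in a group (one family or the total
sample) is `100 * Var_group(score) / Var_group(trait)` averaged over
replicates, with the raw (pre-adjustment) trait variance as denominator
(n-1 throughout; an option uses the adjusted residuals instead). The
published per-gene percentages depend on the non-public GAW17 genotypes and
effect sizes and are treated as qualitative patterns — the package's tests
check the structure (dilution: total-sample share < carrier-family share;
the 2p(1-p)beta^2 closed form in unrelateds) rather than specific numbers.

## Problem sizes in tests and the acceptance script

Closed-form checks are instant. Simulation-based checks use: 100 random
small multi-family datasets for the decomposition identity; 500
one-replicate simulations of the full 697-individual structure for null
calibration; 200 replicates of the default study for the single-carrier
selection rate; 200 independent 300-individual cohorts for the
additive-variance closed form; 0.05-step exhaustive grids on two-trio toys
for optimizer verification. These sizes give Monte-Carlo standard errors
comfortably inside the asserted 3-SE bands while keeping a full run in the
minutes range on one CPU.

## Out of scope

Gene-environment interaction variance components, multipoint linkage,
marker-based IBD estimation, dichotomous traits, X-linked kinship,
genotype-based relationship inference, and selection of more than one
family per replicate.
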
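# Methods

This note documents the statistical machinery, the synthetic-data
generator, the numerical choices, and the limitations of the package.

## Path-model engine

Models are specified in RAM notation: a directed-path matrix `A`
(acyclic, checked by depth-first search with the offending cycle named
in the error), a symmetric covariance matrix `S`, a mean vector, and a
selection filter onto observed variables.  Implied moments are
Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ and μ = F(I−A)⁻¹m.  Parameters are fixed
values or labelled free parameters; sharing a label imposes equality
across entries and groups, and each entry may scale its label (used for
the dizygotic cross-twin genetic covariance, `0.5 × ρ`).

The objective is pattern-wise full-information maximum likelihood: rows
are grouped by missing-data pattern and each pattern contributes
through its count, mean and centred scatter, so the deviance is exact
FIML at one small Cholesky per pattern and its cost is essentially
independent of sample size.  A non-positive-definite implied
covariance returns a large finite penalty (10¹² plus the negative
eigenvalue mass) so line searches can recover.

Optimization is L-BFGS-B with numerical gradients, relative tolerance
1e-8, at most 2000 iterations, and up to five jittered restarts; the
parameter vector is internally rescaled by the start-value magnitudes
so variance parameters (order 1–100) and path coefficients (order
0.01–0.5) are comparably conditioned — without this, runs on
unstandardized data can stall before the gradient is small.
Non-convergence is always reported on the results object; standard
errors are then withheld rather than silently wrong.

Uncertainty: Wald standard errors from the inverse numerical Hessian
of half the deviance.  When a sample drives a variance-component path
to an effective boundary (a Cholesky diagonal at zero), the likelihood
is locally flat — or numerically indefinite — along that direction and
a plain inverse would contaminate every parameter's variance; the
covariance is therefore computed over the well-determined curvature
directions only (eigendirections above a relative floor), i.e.
conditional on the boundary solution, which is the conventional
reporting choice for boundary twin-model fits.  Optionally a CR1
family-clustered sandwich
covariance built from per-family score contributions (numerical
jacobian of casewise log-likelihoods), used wherever rows are
individuals nested in families rather than independent pairs.  Derived
effects (products ab, sums Σab, standardized paths) use the
first-order delta method; standardization rescales each path by the
model-implied standard deviations of its tail and head variables, which
makes the reported effects invariant to affine rescaling of the inputs
(tested).  Confidence intervals are 95% Wald throughout; profile
likelihood is a possible extension.  Likelihood-ratio tests compare
nested fits via the deviance difference; a materially negative
difference raises rather than reporting a spurious zero.

## Twin biometric models

ACE components enter as path coefficients (a, c, e) from unit-variance
latent factors, so variances are squares and no negative-variance
boundary arises; proportions a², c², e² are normalised by their sum and
reported with delta-method intervals.  Cross-twin covariances are fixed
at 1.0/0.5 (A) and 1.0 (C).  The bivariate model uses a
correlated-factors parameterization — free within- and cross-twin
cross-trait component correlations r_g, r_c, r_e (the DZ cross-twin
genetic entry scaled by 0.5) — because those correlations are the
quantities reported, making this preferable to an equivalent-fit
Cholesky.  Falconer's formulas (h² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ,
e² = 1 − r_MZ) serve as an independent closed-form oracle in the tests.
Same-sex and opposite-sex DZ pairs are pooled; sex-limitation models
are out of scope.  The likelihood is pair-level (no double entry).

## MR-DoC models

The polygenic score enters once per twin as an exogenous variable with
free variance, cross-twin covariance fixed at its variance (MZ) or half
of it (DZ, random mating); it is not itself decomposed into A/C/E.
Because MZ co-twins carry literally identical scores, the second
twin's copy is dropped from the MZ likelihood (the pair covariance
would otherwise be exactly singular); no information is lost.

Confounding among exposure, mediators and outcome is carried by a
triangular Cholesky structure over per-trait A (and retained C)
factors, ordered exposure → mediators → outcome; cross-trait E
covariances are fixed at zero.  That E constraint is the
identification assumption that lets the pleiotropic PGS → outcome path
be estimated alongside the causal path; freeing the E covariance
instead is supported (`free_re=True`), but freeing both raises an
identification error.  Shared-environment components of mediators are
constrained to zero by default (`drop_c_mediators`), mirroring the
common instability-driven choice for mediator scales; the constraint
set actually applied is recorded in `constraint_tags`.

The latent-factor variant gives each factor a marker indicator (first
loading fixed at 1), a Cholesky A share and a nonshared disturbance;
each indicator keeps its own additive-genetic and nonshared residual
(indicator shared environment dropped), which is the honest twin
measurement model for composites with residual heritability.

Stratified equality tests fit a four-group model (zygosity × stratum)
twice — mediation paths a/b/c′ free per stratum versus equated — and
compare by LRT; the free fit warm-starts from the constrained solution.
For empirical stratification the pipeline splits pairs by pair-mean
exposure against the median of pair means (keeping families intact);
the calibration and power suites instead assign strata exogenously at
the family level, because median-splitting on the exposure truncates
its distribution and the multivariate-normal likelihood within strata
is then misspecified by construction — an exogenous label isolates the
property actually under test.

## Synthetic cohort generator

Every trait is represented exactly as a loading vector on a basis of
independent unit-variance latent factors tagged A, C, E or PGS, whose
cross-twin correlations are 1/0.5, 1/1, 0/0 and 1/ρ_PGS respectively
(ρ_PGS defaults to 0.5).  Traits are built recursively — exposure from
the instrumental path plus an ACE residual; two latent mediator
factors from the exposure with ACE disturbances, the second blended so
the implied factor correlation hits the configured value exactly;
mediators from factor loadings plus PGS pleiotropy and an unconfounded
specific ACE residual; the outcome from c′, the factor b-paths and
pleiotropy — with every residual scale solved in closed form so each
trait has unit variance exactly.  Exchangeable confounder correlations
(r_a, r_c, r_e) apply to the A/C/E residual components of exposure,
factor disturbances and outcome.  Mediator-specific residuals are
deliberately unconfounded: shared variance among mediators flows only
through the two factors.  An extra exchangeable correlation across all
18 specific residuals would constitute a third common factor that no
two-factor analysis model represents, and pilot runs showed it
destabilises every latent-mediator model fitted downstream — with
trait-level confounding only, mediator-level confounding still arises
through the factors, which is the structure the models assume.

Because the construction is exact, the implied pair covariance of all
traits is available in closed form (`implied_pair_covariance`) and is
used as the analytic oracle in the generator's own tests; sampling is a
single matrix product per zygosity group.

Default generating values are the study conditions the models target:
exposure ACE (1/3, 1/3, 1/3); outcome ACE (0.17, 0.07, 0.76);
instrumental path 0.09; pleiotropic path to the outcome 0.06 (0.03 to
each mediator); factor-level mediation paths a = (0.29, 0.29),
b = (0.17, 0.14), c′ = 0.05; factor correlation 0.45; confounder
correlations r_a = 0.52, r_c = 0.42, r_e = 0 (the bivariate-recovery
setting uses r_e = 0.10 explicitly; the MR-DoC identification
constraint assumes r_e = 0, so that is the default); cohort size 1988
MZ + 3683 DZ pairs.  Mediator-specific residual ACE defaults to
(0.30, 0, 0.70) — shared environment zero, matching the treatment of
most mediator scales.  Factor loadings default to a two-block pattern
(magnitudes 0.3–0.7, signs encoding direction, e.g. well-being loading
negatively on the affect factor) chosen by the implementer, since no
quantitative loading table is available; they are config fields, not
constants.

The measurement layer is optional: with `item_counts` set, each
composite is the mean of 5-point ordinal items (congeneric latent
items, loading 0.85, thresholds at equal-probability normal quantiles
by default with a right-skew preset available) under a ≥50%-observed
rule, with MCAR item nonresponse.  The default is continuous
composites equal to the latent traits: ordinal discretization
attenuates all covariances by roughly the squared item loading, so
parameter-recovery suites target the latent scale, and what they show
is engine correctness under the generating model — not robustness to
coarse measurement, which users can probe with the `realistic` preset.
Missingness is MCAR only (FIML handles it downstream); MAR/MNAR
mechanisms and multiple imputation are out of scope.

## Screening and factor analysis

The association screen is OLS on z-scored variables with CR1
family-clustered sandwich errors — point estimates identical to a GEE
with independence working correlation, inference robust to twin
clustering.  Median splits label strictly-above-median as high, ties
going low (tie counts are reported as observed).  The Bonferroni
threshold is α/m with the conventional half-up 3-decimal rounding
(0.05/18 → 0.003).  Mediator screening requires adjusted-significant
association with both exposure and outcome.

EFA extracts two factors by maximum likelihood (scikit-learn) on
complete-case composites and rotates by promax (κ = 4, Kaiser row
normalization), returning the oblique pattern matrix and factor
correlation; factors are sign-oriented so the dominant loading is
positive.  Promax mildly attenuates moderate factor correlations —
tests bound rather than pin the recovered value.  On genuinely
one-dimensional data rotation spreads the single factor across both
rotated factors with a near-unit factor correlation; the unrotated
solution is the one that shows the second factor vanishing, and both
signatures are tested.  EFA runs on Pearson correlations of composites,
not polychorics on items, consistent with the downstream models
operating on composites.

## Percent mediated

Percent mediated is defined as 100·Σab/(Σab + c′), i.e. relative to
the model-implied total c = c′ + Σab, not to any separately estimated
total.  The ratio is undefined when Σab + c′ = 0 (returned as NaN and
flagged) and is numerically unstable whenever the direct effect is
near zero — intervals on the ratio should then be read with caution.
From rounded two-decimal inputs the ratio can differ by a point from
values computed on unrounded internals (e.g. 0.10/0.14 gives 71.4%
where unrounded internals may print 72%); the package always reports
the unrounded computation.

## Problem sizes in the validation suites

The seeded suites use the smallest problem sizes at which the checked
property is comfortably identified: ACE bias grids at 5000+5000 pairs
(20 replicates), bivariate correlation recovery at 2000+2000 (10
replicates), MR-DoC type-I calibration at 1500+1500 over 200
replicates, LRT calibration at 500+500 over 200 replicates, and the
LRT power check at cohort scale (994 MZ + 1841 DZ per stratum).
Because the FIML deviance works from pattern sufficient statistics,
fit cost is driven by parameter count rather than sample size, so
these choices trade only Monte-Carlo precision.

## Known limitations

- No sex-limitation modelling; DZ same- and opposite-sex pairs pooled.
- No reverse-direction MR-DoC (would need an instrument for the
  outcome) and no assortative mating (DZ PGS correlation fixed at 0.5,
  config-overridable).
- Wald intervals only; bootstrap is used as a cross-check, not a
  reporting option.
- The generator's ordinal layer is congeneric with equal loadings and
  thresholds shared across items; real item batteries are messier.
- Cluster-robust covariances use numerical scores and are O(p·n) per
  fit; they are off by default for pair-level twin models, where the
  pair is the independent sampling unit.
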
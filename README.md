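# twinmediate

Genetically informed mediation analysis on twin cohorts.

`twinmediate` asks a question that ordinary mediation analysis cannot
answer: when an early-life exposure (here, childhood maltreatment)
predicts an adult outcome (intimate-partner-violence victimization)
through intermediate traits such as depressive symptoms or conduct
problems, how much of that pathway survives once genetic and shared
family-environment confounding is taken into account?  It is written
for behaviour-genetics and psychiatric-epidemiology researchers who
work with classical twin designs and polygenic scores.

The package provides, as one coherent toolchain:

- a **seeded synthetic twin-cohort generator** that reproduces the data
  structure such studies rely on — MZ/DZ pair structure, a polygenic
  score entering as an instrument, an exposure, 18 mediator composites
  organised by two correlated latent factors (negative/disordered
  affect; externalizing tendencies), and an outcome, each with its own
  ACE variance decomposition and configurable cross-trait confounding;
- a **multi-group FIML path-model engine** in RAM notation
  (`PathModel` / `PathModelResults`), with pattern-wise handling of
  missing data, equality-labelled parameters across groups, Wald and
  family-clustered sandwich standard errors, delta-method inference for
  derived effects, likelihood-ratio tests and model-implied
  standardization;
- **twin biometric models** (`UnivariateACE`, `BivariateACE`) yielding
  heritability and the genetic / shared / nonshared correlations
  r_g, r_c, r_e, with Falconer's formulas as an independent oracle;
- **phenotypic mediation SEM** (`MediationModel`): simple, parallel
  observed-mediator and latent-factor variants;
- **MR-DoC models** (`MRDoCModel`): Mendelian randomization combined
  with direction-of-causation twin modelling, for baseline causal
  estimation and mediation with observed or latent-factor mediators,
  plus stratified equality tests of mediation paths;
- an **association screen** with family-clustered errors, median-split
  stratification, moderation tests and Bonferroni control; and a
  **CLI pipeline** (`twinmediate all`) that chains
  simulate → screen → factors → mediate → mrdoc → report.

## The models in brief

For a trait y measured on both members of a twin pair, the ACE model
decomposes variance as Var(y) = a² + c² + e², identified by fixing the
cross-twin correlation of the additive-genetic factor A at 1.0 (MZ) /
0.5 (DZ) and of the shared environment C at 1.0.  Mediation follows
the standard decomposition: a (exposure → mediator), b (mediator →
outcome), direct effect c′, indirect effect ab, total c = c′ + Σab,
and percent mediated 100·Σab/(Σab + c′).

MR-DoC embeds that mediation structure in the twin model with a
polygenic score as instrument: per twin, PGS → exposure (instrumental
path), exposure → outcome (causal path), PGS → outcome (pleiotropic
path), with additive-genetic and shared-environment confounding between
traits carried by a triangular Cholesky structure and the cross-trait
nonshared covariance fixed at zero for identification.  All estimation
is full-information maximum likelihood on pair-level data.

## Worked example

```python
from twinmediate import SimulationConfig, generate_cohort, MRDoCModel

cfg = SimulationConfig(n_pairs_mz=3000, n_pairs_dz=3000,
                       ace_mediators=((0.3, 0.0, 0.7),),
                       pleiotropic_mediators=(0.0,),
                       factor_loadings=((0.6, 0.0),),
                       a_paths=(0.0, 0.0), b_paths=(0.0, 0.0),
                       c_prime=0.14, r_e=0.0)
cohort = generate_cohort(cfg, seed=101).standardized()
result = MRDoCModel(cohort).fit(seed=0)
print(result.effects().summary())
```

Output (seed 101):

```
MR-DoC effects (standardized)
======================================================
instrumental (PGS->exposure):  0.086 [ 0.066,  0.106]
causal (exposure->outcome):   0.124 [ 0.074,  0.174]
pleiotropic paths:
           std     se  lower  upper      p
target
outcome  0.058  0.010  0.039  0.077  0.000
constraints: re_xy=0, pleiotropy=free
```

The generating values — instrumental path 0.09, causal effect 0.14,
pleiotropic path 0.06 — are each recovered within their confidence
intervals.  The instrumental path is the PGS–exposure regression the
design leans on; the causal path is the exposure effect net of the
A/C confounding absorbed by the Cholesky structure; the pleiotropic
path is the direct PGS–outcome association the model must allow so the
instrument's exclusion restriction is not assumed blindly.

The same workflow from a shell:

```bash
twinmediate all --demo --seed 1 --out demo_out
```

writes the cohort CSV, the association screen, factor loadings,
mediation tables (phenotypic and MR-DoC), a stratified-test summary
and a JSON manifest with the seed and constraint tags.

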
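# behavar

Bayesian variance partitioning of repeated behavioral measures.

`behavar` is for behavioral ecologists (and anyone analysing repeated
measures with group structure) who need to ask not just *"do groups differ
in average behavior?"* but *"do groups differ in how variable behavior is —
among individuals, and within them?"*. The motivating setting is animal
personality research: individuals from several population-by-sex groups are
each tested repeatedly (e.g. an open-field arena in three contexts), and
the questions are whether groups differ in mean level, in among-individual
variance V_A (behavioral diversity), in within-individual variance V_W
(behavioral flexibility), and in repeatability.

## The model

For trial *j* of individual *i* in group *g*:

```
y_ij = x_ij' β + a_i + e_ij
a_i  ~ N(0, σ²_A[g(i)])        (random intercept per individual)
e_ij ~ N(0, σ²_W[g(ij)])       (residual, "double-hierarchical" part)
```

with fixed effects of population, sex, their interaction, and test context.
Letting σ_A and σ_W be shared or group-specific gives the four-model
candidate set:

| model | σ_A by group | σ_W by group |
|-------|--------------|--------------|
| M1    | no           | no           |
| M2    | yes          | no           |
| M3    | no           | yes          |
| M4    | yes          | yes          |

Models are fitted by a fully conjugate Gibbs sampler (half-Student-t priors
on all SDs via their inverse-gamma scale-mixture representation) and
compared by WAIC and PSIS-LOO computed from the pointwise conditional
log-likelihoods. From the winning model the package derives, draw-wise,
per-group V_A, V_W, repeatability

```
R = V_A / (V_A + V_W)
```

and pairwise posterior contrast tables (ΔV_W, ΔR, Δmean level) with
equal-tailed 95% credible intervals; a contrast is flagged *substantial*
when its interval excludes zero.

A synthetic-study generator reproduces the assumed data structure (default:
four groups of 27/21/16/24 individuals, three contexts each, a shared σ_A
and group-specific σ_W), so the whole pipeline is testable end-to-end
without any field data.

## Worked example

```python
from behavar import (MCMCConfig, ModelSpec, StudyScenario, build_design,
                     fit_mcmc, generate_study, variance_components)

table = generate_study(StudyScenario(seed=1))       # 88 individuals x 3 contexts
spec = ModelSpec.from_id("M3")                      # group-specific residual SDs
design = build_design(table, spec)
samples = fit_mcmc(None, design, spec,
                   config=MCMCConfig(n_chains=2, n_warmup=400, n_samples=800, seed=2))
for s in variance_components(samples):
    print(s.group, s.summary.loc["r", "mean"].round(2))
```

prints (see `examples/02_fit_variance_model.py` for the full script):

```
posterior mean [95% CI] per group:
  PKF:  Vw = 0.44 [0.30, 0.64]   R = 0.32 [0.16, 0.49]
  PKM:  Vw = 0.67 [0.44, 1.01]   R = 0.24 [0.11, 0.39]
  PMF:  Vw = 0.91 [0.58, 1.43]   R = 0.19 [0.08, 0.33]
  PMM:  Vw = 0.52 [0.34, 0.77]   R = 0.29 [0.14, 0.46]
```

PKF (generating residual variance 0.42, the lowest) is recovered as the
least flexible and most repeatable group; PMF (generating 0.73) as the most
flexible. With a stronger 2:1 SD contrast the pairwise table
(`examples/04_contrast_tables.py`) reads:

```
                       PKF                    PKM                    PMF                    PMM
PKF                      -  -0.66 (-1.09, -0.32)*  -0.72 (-1.20, -0.37)*  -0.98 (-1.54, -0.53)*
PKM  -0.29 (-0.41, -0.15)*                      -    -0.06 (-0.59, 0.46)    -0.32 (-0.98, 0.27)
PMF  -0.30 (-0.42, -0.17)*    -0.01 (-0.13, 0.10)                      -    -0.26 (-0.89, 0.35)
PMM  -0.34 (-0.47, -0.20)*    -0.06 (-0.17, 0.05)    -0.05 (-0.15, 0.06)                      -
```

ΔV_W above the diagonal, ΔR below; every cell involving the low-variance
PKF group is starred (substantial), the equal-variance pairs are not.

The `examples/` directory holds one short narrative script per capability
(simulation, fitting, model comparison, contrasts, recovery experiments).
A thin CLI wraps the same stages for shell use:

```sh
behavar simulate --out trials.csv
behavar compare --input trials.csv --trait synthetic_trait
behavar run --config analysis.yaml
```

Real data enter through `read_trials` (long-format CSV: individual,
population, sex, context, trait, value) followed by `run_full_analysis`,
which preprocesses each trait (optional Yeo-Johnson Gaussianization with
per-context exemptions, then standardization), fits M1–M4, compares,
selects, and writes all summary tables plus a manifest that makes the run
bit-reproducible.

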
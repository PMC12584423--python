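# Methods

## Model

`behavar` fits Gaussian mixed models to long-format repeated behavioral
measures in which *both* the mean structure and a variance component carry
predictors (a double-hierarchical, or "distributional", model). For trial
*j* of individual *i*:

    y_ij = x_ij' β + a_i + e_ij,
    a_i  ~ Normal(0, σ²_A[g(i)]),
    e_ij ~ Normal(0, σ²_W[g(ij)]),

where g(·) indexes the four population-by-sex groups (fixed order PKF, PKM,
PMF, PMM). The fixed-effect design uses treatment coding — intercept,
population, sex, population×sex, and context as an unordered factor with
the first (novel-environment) context as baseline — so β is interpretable
as contrasts against the reference cell on the standardized trait scale.
Context is a factor rather than a numeric trial covariate: with three
contexts a factor nests the linear coding and costs one extra degree of
freedom.

The candidate set crosses "σ_A shared vs by group" with "σ_W shared vs by
group" (M1–M4). The group-specific among-individual structure is
implemented as a single random intercept per individual whose prior SD
depends on the individual's group — statistically what "among-individual
variance varies by group" means — not as individual-level slopes over
context. The residual-SD model stores the four SDs directly; with a
saturated group factor this is identical to a log-link regression of σ_W
on the group factor and keeps every SD positive by construction.

All models are nested: forcing the group-specific SDs equal reproduces the
simpler model's likelihood exactly (verified numerically at 1e-12 in the
test suite).

## Priors

Weakly informative defaults, chosen for standardized responses and fully
configurable via `PriorConfig`:

| parameter | prior | default | rationale |
|-----------|-------|---------|-----------|
| each β | Normal(0, s²) | s = 5 | effects beyond ±10 SD units are implausible |
| each σ_A, σ_W | half-Student-t(ν, 0, A) | ν = 3, A = 2.5 | heavy-tailed, weakly regularizing for SDs of a unit-variance trait |

The half-t is represented as an inverse-gamma scale mixture
(σ² | ψ ~ InvGamma(ν/2, ν/ψ), ψ ~ InvGamma(1/2, 1/A²)), which makes every
conditional conjugate.

## Sampling

Metropolis-free Gibbs with exact block updates:

1. (β, a) jointly from their multivariate-normal full conditional given all
   SDs (Cholesky solve of the (p+m)-dimensional precision, assembled from
   per-group cross-product matrices precomputed once);
2. each σ²_W[g] from InvGamma((ν+n_g)/2, ν/ψ + RSS_g/2), then its ψ;
3. each σ²_A[g] from InvGamma((ν+m_g)/2, ν/ψ + Σ a_i²/2), then its ψ.

There is no tuning phase: chains are valid from the first iteration and
warmup only forgets the initial state. Initial SDs are drawn overdispersed
(|t_ν|·A clipped to [0.1, 10]). Per-chain RNG streams are spawned
deterministically from the master seed (`numpy.random.SeedSequence`), so
every run is bit-reproducible; per-trait and per-replicate seeds are in
turn spawned from the analysis master seed.

With an empty response vector every conditional collapses to the prior, so
the sampler reproduces the prior distribution — used as an end-to-end
correctness check, alongside conjugate closed forms and simulation-based
calibration (uniformity of the rank of prior-drawn truths among posterior
draws, chi-square test over 200 reduced-scale replicates).

Convergence is summarized by split R-hat and bulk ESS per scalar parameter
(computed via arviz); defaults warn at R-hat > 1.01 or ESS < 400.
`MCMCConfig` defaults (4 chains, 1000 warmup, 2000 draws) suit final
analyses; the replicate experiments in the tests and the acceptance script
deliberately use shorter single chains (150–400 warmup, 300–800 draws) —
the conjugate blocks mix well enough that selection rates and coverage are
stable at that length, and it keeps whole replicate sweeps cheap.

## Model comparison

WAIC and PSIS-LOO are both computed from the (draws × observations) matrix
of *conditional* log-likelihoods (given the a_i) — the convention of
MCMC-based workflows; a marginal-likelihood WAIC would measure prediction
for new individuals rather than new trials of known individuals and would
rank differently.

* WAIC uses the pointwise-variance penalty (p_waic2) with the n−1 variance
  convention, and SE = sqrt(n · var(pointwise elpd)).
* PSIS-LOO delegates the generalized-Pareto smoothing of the importance
  weights to arviz's reference implementation; per-observation pareto-k
  shape diagnostics are reported and values above 0.7 raise a warning.
  Observations with (numerically) constant log-likelihood get k = 0: their
  LOO contribution is exact.
* Selection takes the maximal elpd, with a parsimony tie-break: any model
  whose deficit against the best is at most half the paired SE of the
  difference counts as tied, and ties go to the simpler model in the order
  M1 < M2 < M3 < M4. Both the WAIC-based and LOO-based rankings are
  reported, with disagreement flagged (the LOO choice is used downstream
  when they disagree).

In hierarchical models with per-individual intercepts, a handful of
high-leverage trials routinely exceed k = 0.7 at moderate draw counts; the
warnings are informative, not fatal, and the WAIC ranking is unaffected.

## Derived quantities

V_A = σ²_A, V_W = σ²_W, and R = V_A/(V_A+V_W) are computed per retained
draw, never from summarized moments. Group contrasts (ΔV_W, ΔR, Δmean
level) difference the *paired* draws per iteration and then summarize;
means match difference-of-means exactly while intervals account for the
posterior correlation between groups. Intervals are equal-tailed quantile
intervals (not HPD), matching mainstream Bayesian regression software.
"Substantial" = the 95% interval excludes zero; this is the standard
credible-interval convention for bolding contrasts in this literature,
which never states a sharper rule.

ΔR entries can be NA-flagged when either group's V_A is indistinguishable
from zero (repeatability differences are then not interpretable). Because
posterior V_A draws are strictly positive, "indistinguishable" is
operationalized as the lower 2.5% quantile falling at or below
`va_zero_tol` (default 0, i.e. the flag fires only for degenerate draw
sets; analyses of near-zero-V_A traits should set a small positive
tolerance). The raw contrast value is always retained alongside the flag.

For model specs with a shared component, every group receives the same
draws for it, so its contrasts are exactly zero — the structural statement
that the groups do not differ under that model.

## Synthetic studies

`StudyScenario` defaults define the reference conditions: group sizes
27/21/16/24 (PKF/PKM/PMF/PMM), 3 contexts per individual, no missingness
(the emulated design is balanced; missingness, when enabled, is completely
at random). The default variance pattern is heteroscedastic-residual
(M3-type): shared σ_A = 0.63 (V_A ≈ 0.4) and σ_W = (0.65, 0.79, 0.85,
0.78), i.e. V_W ≈ (0.42, 0.62, 0.73, 0.61). These were chosen so that, on
a standardized scale with total phenotypic variance near 1, the pairwise
V_W differences against the first female group are ≈ (0.20, 0.31, 0.19) —
the magnitude of sexually dimorphic flexibility differences reported for
activity traits in the two-island lizard system this design emulates.
Population, sex and interaction effects default to zero (no mean-level
differences); context effects default to a modest habituation pattern
(−0.3, −0.15) since repeated exposure typically damps activity.

At these effect sizes a single study-sized dataset yields only *marginal*
evidence: contrasts hover at the edge of substantiality and the parsimony
tie-break sometimes returns the null model even when the heteroscedastic
model has the best raw elpd. That is a property of the design, not a bug,
and is why the acceptance script reports replicate *rates* alongside
single-run outcomes, and why the stronger 2:1 SD ratio (σ_W = (0.5, 1, 1,
1)) is used where a clearly identifiable structure is needed.

What the generator does **not** emulate: non-Gaussian raw traits (the
generator produces already-Gaussian values, so the Yeo-Johnson stage is
exercised on separately constructed skewed samples), context-by-individual
interactions (no individual slopes), informative missingness, measurement
error, and any trial-order or carry-over effects. Passing tests therefore
certify the statistical machinery under the model's own assumptions, not
robustness to their violation.

## Preprocessing

Raw trait columns are optionally Gaussianized by a Yeo-Johnson power
transform (parameter by maximum likelihood; chosen over Box-Cox because
standardized values can be zero or negative), with specific contexts
exemptable per trait — mirroring designs in which one trait × context
combination is already Gaussian. Transformation precedes standardization
(to sample mean 0, SD 1, n−1 convention, over the whole trait column across
groups and contexts). Every step is stored in an invertible
`PreprocessRecord`; round trips recover raw data to 1e-8 relative
tolerance, using expm1/log1p forms that remain stable near the λ = 0 and
λ = 2 branch points. If the transform's optimizer fails, the identity
transform is kept with a warning.

## Numerical and edge-case conventions

* Degenerate inputs: constant trait columns and zero-total-variance
  repeatability raise typed errors; proposals with σ ≤ 0 get log-prior
  −inf rather than an exception.
* A non-positive-definite location precision or non-finite sampler state
  aborts with a diagnostic state dump (chain, iteration, current SDs).
* Rank-deficient fixed-effect designs error before sampling, naming the
  offending term when a factor has a single observed level.
* Individuals with a single trial are retained (they inform V_A weakly and
  V_W not at all); the mixed-model likelihood handles unbalanced data
  naturally.
* The sampler requires n ≥ p + 2 observations when data are present; n = 0
  is explicitly allowed (prior reproduction).

## Known limitations

* Gaussian likelihood only; no censoring, measurement-error or
  non-Gaussian families.
* One random-effect level (individual); no crossed or nested designs.
* WAIC/LOO on the conditional likelihood answer "predict new trials of
  known individuals"; for "predict new individuals" a marginal criterion
  would be needed.
* The exact Gaussianizing transform and prior scales used by any particular
  published analysis are rarely recoverable from a paper's text; results
  can be sensitive to these choices, which is why both are explicit,
  serialized configuration here.
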
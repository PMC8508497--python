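# Methods

## Stage 1: output-oriented BCC efficiency scores

Each decision-making unit (DMU) is scored by the linear program in the
README: maximise the proportional output expansion φ attainable by a
convex combination of peers that uses no more of any input. The convexity
constraint Σλ = 1 makes the technology variable-returns-to-scale (the BCC
model); without it the model would be the constant-returns CCR variant,
which is out of scope here, as are input orientation, slack-based
measures, scale efficiency and bootstrap corrections of the scores.

Numerical choices:

- The LP is solved with HiGHS (`scipy.optimize.linprog`) at feasibility
  tolerance 1e−8 over the joint variables (φ, λ). The evaluated unit
  itself (λ_self = 1, φ = 1) is always feasible, so infeasibility cannot
  occur for valid data and is treated as an internal error.
- φ is clipped to max(φ, 1) before inversion so that PTE = 1/φ stays in
  (0, 1] under solver noise.
- A unit is "on the frontier" when PTE ≥ 1 − `frontier_tol` (default
  1e−6, configurable). Exact ties are all counted as efficient.
- Inputs and outputs must be finite and strictly positive; zero or
  negative entries are rejected at dataset construction. No
  translation-invariance devices are used.
- Degenerate optima are possible: only φ is unique; the intensity vector
  λ is reported as found by the solver.
- Any input standardization (e.g. expressing purchases per bed) is the
  caller's responsibility; the DEA layer consumes final matrices.

Correctness is checked against an independent oracle that enumerates all
basic solutions of the LP (every support of active constraints), on
hundreds of small random datasets.

## Stage 2: multilevel zero-one inflated beta regression

PTE is continuous on (0, 1) with an atom at 1 (frontier units), so the
response is modelled as a three-part mixture: endpoint with probability
ω01 (then 1 with conditional probability θ, else 0), otherwise
Beta(µ·φ_B, (1−µ)·φ_B) in the mean/precision parameterisation. Both µ and
ω01 get logit-linear predictors in the unit-level (level 1) and
group-level (level 2) covariates; only the µ-submodel carries a group
random intercept u₀ⱼ ~ N(0, σ²ᵤ₀). Keeping the ω01-submodel free of
random effects is a deliberate fidelity choice to the model as published;
θ and the precision are constant across units.

Observed responses within `endpoint_tol = 1e−6` of an endpoint are
snapped to it before likelihood evaluation: the discrete mass lives on
exact endpoints and LP rounding noise from stage 1 must not leak into the
continuous component. Zero responses are supported by the likelihood even
though DEA cannot produce them (generators may emit them).

### Priors

The published description of the priors is terse ("improper flat priors
for all fixed effects and normal distribution for the variance of the
random error"). A normal prior on a *variance* has negative support, so
the default configuration reads it in the standard way:

| parameter    | default prior        | rationale |
|--------------|----------------------|-----------|
| fixed effects (β, γ) | improper flat | as published |
| σ_u0         | half-normal(scale 2.5) | weakly informative on an sd of a logit-scale intercept |
| θ            | uniform(0, 1)        | unstated in the source; proper and flat |
| precision φ_B | half-normal(scale 50) | unstated; covers the plausible range (≈ 14) with heavy slack |

`gamma_sensitivity` and `normal_sensitivity` configurations swap the
σ_u0/precision priors for gamma and positive-truncated normal forms, for
sensitivity analysis; all scales are configurable.

### Sampler

An adaptive random-walk Metropolis-within-Gibbs scheme, exploiting the
likelihood factorisation (interior beta part / endpoint-membership part /
1-vs-0 part):

- β-block and γ-block: multivariate normal proposals with Haario-type
  empirical covariance (scaled 2.38²/d) and Robbins–Monro step scaling
  toward 0.234 acceptance; three sweeps per iteration because these
  correlated blocks are the mixing bottleneck.
- Random intercepts: jointly proposed, accepted per group (groups are
  conditionally independent), per-group step sizes tuned toward 0.44.
- A recentering move β₀ → β₀ + c, u → u − c walks along the
  intercept/random-effect ridge; the likelihood is invariant, so only the
  u-prior enters the ratio. Without it the intercept mixes an order of
  magnitude slower.
- Scalars logit(θ), log(φ_B), log(σ_u0) with tuned scalar steps
  (transform Jacobians included in the target).
- Adaptation runs during warmup only and is then frozen, so retained
  draws come from a fixed-kernel chain. Step scales are clamped
  (log-scale ∈ [−10, 4]) so that unidentified directions (e.g. γ on data
  with no endpoints) cannot blow up the proposal.
- Initialisation: fixed effects 0, σ_u0 = 1, θ = 0.9, precision = 10,
  u = 0, each jittered N(0, 0.1) per chain; up to 100 redraws if the
  log-posterior is non-finite.
- Defaults mirror the published protocol: 4 chains, 1000 warmup, 5000
  retained iterations; per-chain generators are spawned from the master
  seed, so runs are bitwise reproducible. An optional `thin` keeps every
  k-th post-warmup iteration.

### Summaries and diagnostics

Posterior summaries pool post-warmup draws across chains: mean, sd,
empirical 2.5/97.5 percentiles (linear interpolation), PCP = fraction of
draws strictly > 0 (draws exactly 0 count as negative, making PCP + NCP
= 1 exact), and ratio = exp(mean) for regression coefficients. R̂ and
bulk/tail ESS use the rank-normalised split-chain formulation (computed
via `arviz`); constant draws yield NaN with a warning. The convergence
verdict applies R̂ < 1.01 and ESS > 400 per monitored parameter.

## Synthetic data

The hospital dataset the method was developed on is not publicly
deposited, so the generators emulate its structure:

- `simulate_hierarchy`: J groups of configurable (possibly unbalanced)
  sizes; standard-normal quantitative covariates at both levels (drawn
  standardized rather than re-standardized); one 3-level ownership factor
  (public / private / public-private partnership) dummy-coded against
  "Public", with configurable prevalences or exact counts.
- `simulate_zoib`: the generative reading of the mixture, with random
  intercepts drawn once per group unless fixed.
- `simulate_production`: a planted Cobb–Douglas technology
  g(x) = 5·Πxᵢ^{0.2} (exponents sum to 0.8 < 1, i.e. decreasing returns,
  so the variable-returns DEA model is the correct class). Unit sizes are
  log-normal(0, 0.5), inputs scale with size times log-normal(0, 0.15)
  noise, outputs split in fixed proportions. Outputs are shrunk by an
  inefficiency factor δ: 1 with probability 0.155, else Beta(5.8, 2.55).
  Since δ = 1 units lie exactly on a concave frontier, DEA provably
  scores them 1; measured PTE of the rest exceeds δ because the empirical
  hull lies inside the true technology. The constants are calibrated so
  that at n = 173 the measured regime matches the reference study: mean
  PTE ≈ 0.78 and ≈ 18.5% of units on the frontier.
- `scenario_table3`: the reference regime — 173 units in 17 groups
  (multinomial-uniform sizes, at least one unit per group; the true
  regional distribution of hospitals is unpublished), ownership counts
  exactly 147/12/14, one quantitative covariate per level, and true
  parameters set to the published posterior means (β intercept 1.00,
  ownership effects 1.45/0.64, γ intercept −3.00, ownership effects
  3.74/2.10, θ = 0.97, precision 14.27, σ_u0 = 0.57). Under these values
  the implied response distribution itself sits at mean ≈ 0.78 with
  ≈ 18% ones, matching the published regime without further tuning.

What the generators do **not** emulate: real case-mix adjustment,
monetary deflators, the actual regional sampling frame, or correlation
between covariates and the DEA inputs/outputs. Passing tests therefore
demonstrate correctness of the algorithms and calibration of the regime,
not reproduction of the original data-dependent estimates (mean PTE 0.78,
32 frontier hospitals, the published coefficient values), which cannot be
recomputed without the source data.

## Pipeline conventions

- Quantitative level-1 covariates are standardized over the n units;
  level-2 covariates are standardized over the J distinct group values
  (they are regional attributes — "one standard deviation" is meant at
  the regional level) and broadcast back to units. Standardization uses
  the sample sd (n − 1) and fails loudly on constant columns.
- Factors are dummy-coded against a declared reference level, rendered as
  "Reference" rows in the report.
- The DEA and regression stages are decoupled: a precomputed PTE column
  can be supplied instead of running DEA, so the regression can be
  validated independently.
- End-to-end runs are deterministic given (config, seed): output CSV/JSON
  files are byte-identical across repeats.

## Problem sizes used in the test suite

Oracle comparisons use hundreds of random DEA instances with n ≤ 6 units
(basic-solution enumeration is exponential). The recovery suite fits 20
replicates of `scenario_table3` at a reduced per-chain size of 1000
retained draws (thinned ×4 from 4000 post-warmup iterations) — small
enough to run routinely while keeping quantile estimates stable. The
acceptance script runs one reference-scenario fit at the full published
protocol (4 × 1000 + 5000).

## Known limitations

- With improper flat priors on fixed effects, categories with few units
  (12–14 of 173) and large true effects in the frontier submodel, the
  posterior for the corresponding dummy coefficients is biased away from
  zero in repeated sampling, and the recovery suite observes ~85%
  frequentist coverage of the 95% credible intervals for those two
  coefficients (the other eleven parameters meet their checks). Data
  realizations in which a small category has no frontier units at all
  produce complete separation, under which the flat-prior posterior is
  improper and the sampler drifts; such runs are identifiable by their
  extreme credible intervals. A weakly-informative prior on the fixed
  effects would remove both effects but would depart from the published
  specification, so it is not the default.
- The random-walk sampler is adequate for the ~35-parameter models here;
  much larger covariate sets would warrant a gradient-based backend,
  which can be substituted as long as it honours the same diagnostics
  contract.
- Only the µ-submodel carries a random intercept; random slopes,
  variable precision/θ submodels and maximum-likelihood fitting are out
  of scope.
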
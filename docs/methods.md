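# Methods

## Model and estimand

Each trial is a two-arm parallel-group randomised trial analysed with an
exponential proportional-hazards regression: participant *j* has hazard
`η_j = exp(α + β x_j + γ z_j + λ x_j z_j)` with treatment indicator `x`,
covariate `z`, prognostic effect `γ` (log hazard ratio per covariate unit)
and interaction `λ` (change in treatment log hazard ratio per covariate
unit). The estimand throughout is `λ`; the planned meta-analysis pools the
per-trial estimates `λ̂_i` under a common-effect model, and the deliverable
is the power of a two-sided Wald test of `λ = λ*` for a user-specified
minimally important `λ*`.

The exponential model is a working assumption chosen because its observed
information matrix has a closed form, `I = Σ_j w_j d_j d_jᵀ` with
`d_j = (1, x_j, z_j, x_j z_j)` and `w_j = t_j exp(μ_j)` (t the observed time,
event or censoring). On data with a roughly constant hazard, interaction
estimates and standard errors from Cox regression are nearly identical
(the package's test suite confirms this on simulated data against
`lifelines`); under strong hazard non-constancy the approximation degrades
and the power estimate inherits that error.

## Aggregate-data approximation

`I_i = n_i · I*_i` with `I*_i = E[w d dᵀ]` over the joint distribution of
arm, covariate and weight; `var(λ̂_i) = [I*_i⁻¹]₍₄,₄₎ / n_eff`. The three
weight options differ in how the unobservable `exp(y)` is filled in:

- **Option (i)** — `w ≡ 1` with `n_eff = e_i` (the event count). This is the
  no-censoring identity E[w] = 1 (at the true parameters, `t·exp(μ)` is a
  unit exponential draw) with the effective sample size discounted from
  participants to events. Needs only counts.
- **Option (ii)** — `w = f_arm · exp(μ̂)` with `n_eff = n_i`, where
  `α̂ = ln(e_C/(n_C f_C))` (control log event rate), `β̂` the aggregate log
  rate ratio (treatment over control), and `γ, λ` taken from the scenario.
  Needs per-arm mean follow-up.
- **Option (iii)** — as (ii) but `exp(y)` is the (arm × binary covariate
  level) subgroup mean follow-up, given as absolute values or as offsets
  from the arm means. Binary covariates only; the required subgroup
  follow-ups are rarely published.

The covariate is centred by its pooled (across arms, size-weighted) mean in
every code path. For option (i) the (4,4) element of the inverse information
is algebraically invariant to centring; for options (ii)/(iii) centring
defines what `α̂` and `β̂` refer to (a participant at the mean covariate),
and the pooled mean — rather than per-arm means — is used so that any arm
imbalance in the covariate remains visible to the design.

### Evaluating the expectation

Two interchangeable routes compute `I* = E[w d dᵀ]`:

- **Analytic (default).** Binary covariate: a weighted sum over the four
  (arm × level) cells. Continuous covariate: per-arm normal moments; under
  option (ii) the weight tilts the arm's normal by `exp(cz)` with
  `c = γ + λx`, and the tilted-normal identities
  `E[e^{cz}] = e^{cm + c²s²/2}`, tilted mean `m + cs²`, unchanged variance
  `s²` give exact first and second moments. This covers every supported
  option/covariate combination (option (iii) is binary-only by
  construction), so the default outputs carry no simulation noise.
- **Monte Carlo.** Simulates a large cohort (default one million): arm
  indicator Bernoulli(n_T/n), covariate from the arm's distribution, weight
  per the chosen option, and averages the per-participant contributions
  `w d dᵀ`. Deterministic given the scenario seed, which is recorded in the
  per-trial output. The covariate is centred by its population pooled mean
  (not the simulated sample mean) so the Monte Carlo estimand coincides
  exactly with the analytic one; the reported MC standard error of
  `var(λ̂)` is the delta-method linearisation `δvar = −uᵀ δI* u` with
  `u = I*⁻¹ e₄`, i.e. the standard deviation of `w (uᵀd)²` over the cohort,
  divided by √N and by the effective sample size.

The test suite cross-checks the two routes on every fixture trial at one
million participants within three MC standard errors. Because forty
simultaneous three-sigma comparisons fail by chance for roughly one seed set
in ten even when the estimator is exact, an exceedance is confirmed once at
an independent seed with a four-million cohort before the test fails.

### Numerical choices and degenerate inputs

- Information matrices are inverted with `numpy.linalg`; a condition number
  above 1e10 emits a near-singular warning, exact singularity raises.
- Any joint (arm × level) cell probability below 1e-6, or an arm with zero
  events under options (ii)/(iii), aborts with a message recommending
  option (i); no silent continuity correction is applied because none has a
  principled default.
- The Wald power uses the exact normal quantile `z_{1−α/2}` (1.959964 at
  α = 0.05) rather than 1.96, so `power(λ=0) = α` holds exactly; the
  difference in reported power is below 1e-5.
- Reported per-trial variances are computed from unrounded intermediates;
  printed reports round to 4 significant figures (variances) and one
  decimal (powers, weights), with full precision always in the JSON output.

## Maximum-likelihood oracle

`fit_mle` maximises `ℓ = Σ_j [event_j μ_j − t_j e^{μ_j}]` by Newton–Raphson
with step-halving; initial values come from the null model
(`α = ln(total events/total time)`, others 0), and convergence requires the
score max-norm below `tol · max(1, total events)` (default tol 1e-8) — the
event count is the natural scale of the score, making the criterion
sample-size invariant. Zero-event margins (an arm, a binary-covariate level,
or an arm × level cell with no events) are detected up front and raised as
separation, since the corresponding coefficient diverges; a parameter
passing |20| on the log scale during iteration raises likewise. Times must
be strictly positive; degenerate inputs are rejected rather than floored.
The observed information at the estimate equals the negative Hessian of the
log-likelihood (verified by finite differences in the tests), and its
inverse is the reported covariance.

## Synthetic-IPD generator

The generator emulates a two-arm trial whose aggregate profile is given:
arm assignment Bernoulli(n_T/n); covariate binary or per-arm normal
(continuous covariates are generated already centred); event times
exponential with rate `exp(μ(truth))`; censoring by one of three
mechanisms — per-arm uniform(0, b) administrative censoring (default),
a fixed per-arm horizon, or per-arm exponential censoring. The mechanism
parameter is calibrated by one-dimensional root finding (Brent) so the
expected event fraction, integrated over the arm's covariate distribution
by Gauss–Hermite quadrature, matches e/n exactly; an event fraction of one
returns the no-censoring limit. Uniform censoring was chosen as the default
because it mimics staggered administrative follow-up and reproduces a mean
observed follow-up close to the published f; exponential censoring is
offered because its event fraction `η/(η+c)` is closed-form and makes the
calibration testable to 1e-10.

What the generator does **not** emulate: non-constant baseline hazards,
informative censoring, covariate measurement error, non-normal continuous
covariates, and within-trial correlation structures. Passing validation
therefore shows the aggregate approximation recovers the information of an
exponential-world IPD analysis; it does not certify behaviour under model
misspecification, which should be assessed per application (the Cox
cross-check gives partial reassurance for modest hazard non-constancy).

The SE agreement study simulates fresh datasets per sample size (not
resamples of one dataset), fits each replicate, and reports the mean
model-based SE, the empirical SD of `λ̂` across replicates, each requested
option's approximate SE (scaled from the full-size variance by n/size), and
their ratios; it fails if more than 5% of replicate fits fail.

### Validation study sizes

The packaged validation profile is a realistic mid-size trial: n = 2000,
balanced arms, a 50/50 binary covariate, control event rate 0.15/year,
treatment hazard ratio 0.8, interaction hazard ratio 1.3, uniform(0, 5 y)
censoring (≈ 27% of participants with events, mean follow-up ≈ 2 years).
Agreement checks use 200 replicates; the SD-versus-model-SE calibration
check uses 600 replicates because the SD estimator's own relative noise at
200 replicates (~5.5%) makes a ±10% band a coin-flip rather than a test —
600 replicates bring the check to roughly three standard errors.

## Scope and design decisions

- Common-effect pooling only; between-trial heterogeneity in λ, random
  effects and prediction intervals are out of scope, as are one-stage IPD
  models, non-linear interaction trends, multi-covariate adjustment, and
  reconstructing follow-up distributions from published Kaplan–Meier curves.
- The interaction `λ` is stated per `unit_scale` covariate units (e.g. per
  10 years) and attached to the covariate specification, while `γ` is per
  single unit; keeping the scale with the covariate prevents silent unit
  errors when variances (per unit²) and effects (per 10 units) mix.
- Covariate summaries published only overall may be duplicated into both
  arms (`CovariateSpec.*_overall`), justified by randomisation.
- Arm-level covariate summaries are canonical when both arm-level and joint
  summaries could be formed; joint cells are derived as (arm share) ×
  (within-arm proportion).
- The analytic expectation is used wherever it exists (all supported
  cases), with Monte Carlo as an explicitly requested alternative; this
  keeps primary outputs deterministic while the simulation route remains
  available and continuously cross-checked.
- One known blemish in the shipped example's reference results: the
  published per-trial table's trial-2 age standalone power is inconsistent
  with its own variance under the stated λ (it implies ≈ 8%, not ≈ 88%);
  the package's tests treat that single cell as a typographical error and
  assert all other cells.

## Known limitations

- Power is conditional on the assumed λ, γ and the exponential working
  model; it is an approximation, not a guarantee (approximate SEs were
  within ~2% of the oracle in the packaged validation, but published
  comparisons of such approximations against Cox analyses of real trials
  report discrepancies up to ~20% in small samples).
- Option (i) ignores differential follow-up between arms entirely;
  option (ii) ignores within-arm follow-up variation; both understate or
  overstate information when censoring is strongly covariate-dependent.
- Continuous covariates are modelled as per-arm normal; heavy skew should
  be transformed before summarising, or the Monte Carlo route extended with
  a custom distribution.
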
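# Methods

## Model

### Censored detection likelihood

A monitoring station is one ephemeral resource unit placed in front of a
camera. For each analyzed species the station yields exactly one record
`(t, c)`: the first-detection time in days (`c = 0`) or the censoring time
(`c = 1`; the rival used the resource first, the camera failed, or the
survey ended — the cause is kept only as reporting metadata and never enters
the likelihood). With occupancy probability `ψ ∈ [0, 1]` and detection-time
density `f(·|θ)` on `(0, ∞)` (survival `S = 1 − F`), the record contributes

```
log L = (1 − c) · [log ψ + log f(t)]  +  c · log(1 − ψ + ψ S(t))
```

The occupancy mixture is already marginal — no latent presence indicator is
sampled. Species enter as independent factors (detection of an unpredictable
resource is assumed independent across species; a rival's use appears only
through censoring), so the joint log-likelihood is a sum over species and
stations and extends unchanged to three or more competitors. The censored
mixture term is evaluated as `log1p(−ψ · (−expm1(log S)))`, which is exact
for small `ψ(1 − S)` and degrades gracefully to `−inf` at the boundary
(`ψ = 1`, `S = 0`) — a zero likelihood is returned, not raised.

Four detection-time families are supported, parameterized the way field
studies report them: exponential by rate `λ` (per day), gamma by shape and
rate, log-normal by `(μ, σ)` of log-days, Weibull by shape and scale. All
densities, distribution functions and hazards are delegated to
`scipy.stats`; the hazard `f/S` is computed on the log scale so it stays
finite deep in the right tail.

Ties (two species uncensored at the same station) have probability zero
under the continuous-time model; the loader rejects them by default and,
with `allow_ties=True`, keeps both detections and warns.

### Ecological metrics

For a focal species A, rival B and availability window `v` (the time at
which the resource abruptly becomes unusable; `v = ∞` for gradually decaying
resources):

- Competition Intensity `CII_A = ψ_B ∫₀ᵛ F_B(u) f_A(u) du`. As printed this
  carries no `ψ_A` factor — it is the share lost *conditional on A being
  present*; the `ψ_A`-multiplied unconditional version is available by
  multiplying the result, and the Monte-Carlo oracle exposes an
  "any-rival-first" extension (`cii_all_rivals`) for ≥ 3 species, computed
  by event counting only.
- Potential Functional Contribution `PFC_A = ψ_A F_A(v)`.
- Unique Functional Contribution `UFC_A = PFC_A (1 − PFC_B)`; the subtracted
  `PFC_A · PFC_B` is the functionally redundant share and is exposed
  separately.
- Resource allocation
  `∫₀ᵛ ψ_A [1 − ψ_B + ψ_B S_B(u)] f_A(u) g(u) du`, the expected fraction of
  the resource's initial value captured by A under value decay `g`.

Two algebraic identities tie these together and are enforced in tests:
`UFC_A + PFC_A·PFC_B = PFC_A` exactly, and `allocation(g≡1) + ψ_A·CII_A =
PFC_A` to quadrature tolerance.

### Gompertz value decay

Remaining value (wet mass as a fraction of the day-0 mass) follows the
decreasing Gompertz

```
g(t) = 1 − (1 − γ) · exp(−exp(−β (t − α)))
```

with inflexion time `α` (days), slope `β > 0` (per day) and equilibrium
fraction `γ ∈ (0, 1)`. Observed proportions are modeled as
`y ~ Gamma(shape = d, rate = d / g(t))`, so `E[y] = g(t)` and `d` is a
dispersion (squared coefficient of variation `1/d`). Each resource is
normalized by its earliest measurement; resources with no day-0 baseline
are excluded with a warning, and the baseline rows themselves (identically 1
by construction) are excluded from the likelihood. Proportions are pooled
across resources — no per-resource random curves, matching the small sample
sizes these studies have.

## Inference

Sampling uses adaptive random-walk Metropolis on an unconstrained space
(logit for `ψ` and `γ`, log for rates, shapes, scales and dispersion,
identity for the log-normal `μ` and the inflexion `α`), with the appropriate
Jacobian terms added to the log-prior. During warmup the proposal covariance
is re-estimated from the chain history three times (Haario-style, with a
small diagonal jitter) and the global step size is tuned toward a 30%
acceptance rate by Robbins–Monro updates; after warmup the proposal is
frozen so the kept draws form a valid Markov chain. Chains are fully
independent given the seed (independent `SeedSequence` streams), which is
what split-R-hat assumes. A gradient-based sampler would mix faster per
iteration, but for these 4–8-parameter posteriors the adapted random walk
reaches effective sample sizes of hundreds within seconds, and its posterior
medians agree with an independent affine-invariant ensemble sampler (emcee)
run on the identical log-posterior — that agreement is a test.

Defaults mirror the conventional field protocol: 5 chains × 5000 iterations
with 2000 warmup; convergence requires split-R-hat < 1.1 for every
parameter (computed by `arviz`, together with bulk ESS). All tests and the
acceptance script use shorter, explicitly stated runs because the posteriors
involved are small and well-behaved; problem sizes are listed below.

Default priors (all overridable): `ψ ~ Uniform(0, 1)`; positive TTD
parameters `~ half-Normal(5)` on the natural per-day scale; log-normal
`μ ~ Normal(0, 5)` and `σ ~ half-Normal(2.5)`. For the decay model:
`α ~ Normal(0, 50)` days, `β ~ half-Normal(5)`, `γ ~ Uniform(0, 1)`, and
`dispersion ~ half-Normal(100)` — wider than the generic positive-parameter
prior because realistic mass series have `d` of order 10–100 (10–30%
multiplicative noise), which a scale-5 half-normal would truncate.

WAIC is computed from the stored per-record pointwise log-likelihood matrix
as `−2 (lppd − p_waic)` with the pointwise-variance penalty, using the
unbiased `1/(n−1)` variance estimator (the convention of the R `loo`
package; `arviz` uses `1/n`, an exact known rescaling that the
cross-implementation test accounts for). The standard error follows from
the scatter of pointwise elpd contributions. Family comparison fits each
candidate family with a deterministically derived seed and ranks by WAIC;
non-converged fits stay in the table but are flagged.

## Numerical choices

- Metric integrals use `scipy.integrate.tanhsinh` (adaptive tanh-sinh
  quadrature, absolute/relative tolerance 1e-10, achieved error checked
  against 1e-8), which is vectorized and robust to the integrable endpoint
  singularities of gamma/Weibull densities with shape < 1.
- `v = ∞` is handled by truncating at the `1 − 1e-10` quantile of the focal
  species' distribution (every integrand is bounded by `f_A`) and adding the
  corresponding tail bound; for the exponential family this matches the
  untruncated closed forms to 1e-8.
- Posterior metrics are evaluated draw-by-draw; the quadrature-based ones
  (CII, allocation) accept `max_draws` for even thinning. Decay draws are
  paired with TTD draws by index after one seeded permutation (the two
  posteriors come from independent fits), recycling the shorter sequence.
- The predictive remaining-mass histogram draws, per simulated resource
  unit, one posterior parameter set, occupancy indicators and latent times;
  the outcome is 0 if the focal species is absent, beaten by the rival, or
  outside the window, and otherwise the remaining-value proportion at
  arrival. By default the gamma observation model generates that proportion
  (clipped to 1, since a proportion of initial value cannot meaningfully
  exceed one) — this is what makes the published-style histogram's clipping
  rule meaningful; `observation_noise=False` uses the mean curve `g(T_A)`
  instead, which is the variant whose mean converges to the allocation
  integral.
- CSV writers emit full-precision `repr` floats and readers parse with
  `float_precision="round_trip"`, so datasets round-trip exactly and
  pipeline reruns are byte-identical.

## What the simulator emulates — and what it does not

`simulate_ttd` draws, per station: independent occupancy per species, latent
first-detection times for occupied species, an optional exponential
camera-failure clock, and a survey end; the earliest occupied species' time
(if it beats failure and survey end) is recorded uncensored and censors all
rivals at that moment. This is exactly the model's own generative process
plus the two administrative censoring causes. It deliberately omits features
real surveys can have: spatial correlation between stations, year effects
(pooling is the caller's responsibility), behavioral interference or
avoidance between species, repeated visits to resources that survive first
use, and covariates on `ψ` or `θ`. Passing recovery and coverage tests
therefore show that the estimator inverts its own data-generating process at
realistic sample sizes — not that real data meet the independence
assumptions.

`simulate_decay` gives each resource a lognormal initial mass (default mean
5 kg, CV 0.2, the scale of a mesocarnivore carcass), recorded exactly at
day 0 — the placement weighing later proportions are normalized by — and
gamma-noisy masses around `g(t)` thereafter.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own trade-off between evidence and turnaround:
two-species recovery at K = 300–400 stations with 3 chains × 1200
iterations (500 warmup); interval-coverage and WAIC-selection studies at
10–20 replicates; Monte-Carlo oracle agreement at 10⁶ draws per parameter
set (3 SE criterion); Gompertz recovery at the field scale of 21 resources
measured daily for a month. The acceptance script completes in roughly a
minute on one CPU.

## Known limitations

- Metropolis sampling needs longer runs than NUTS would for strongly
  correlated or weakly identified posteriors (e.g. `ψ` near 1 with heavy
  censoring); the R-hat gate reports this rather than hiding it.
- The pairwise metrics follow the two-species definitions; with ≥ 3 species
  they are computed per ordered pair, and only the Monte-Carlo
  `cii_all_rivals` extension aggregates rivals.
- A station that was never visited and whose camera never failed is censored
  at the survey end; the survey length is therefore part of the design and
  must be finite unless every station is guaranteed a detection.
- The decay model pools proportions across resources and models no
  nutrient-specific decay.
- Plug-in metrics evaluated at posterior *medians* need not equal the
  posterior *median of the per-draw metric* when the posterior is skewed or
  correlated; `posterior_metric` computes the latter, which is the
  recommended summary.
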
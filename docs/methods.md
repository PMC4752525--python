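# Methods

## Data model

The unit of analysis is the *gap time*: the at-risk interval, in weeks,
between a hospital discharge and the next admission.  The first gap runs
from disease onset to the first admission; time spent in hospital is
excluded from the time scale, since patients under inpatient treatment are
not at risk of readmission.  Each subject contributes gaps of rank
k = 1, 2, …, all ending in an observed relapse (δ = 1) except possibly the
last, which is right-censored (δ = 0) when follow-up closes mid-interval.
Covariates are measured at baseline and treated as time-fixed: age at onset
(raw years), and indicators for male gender, single marital status, gradual
onset, head injury, and family history (the reference levels are female,
married, sudden, no, no; the indicator is 1 for the first-named level).

Time is real-valued in weeks.  Zero-length gaps (readmission on the day of
discharge) are rejected as validation errors rather than floored: the
continuous-time likelihood requires t > 0, and silently perturbing data
would hide a recording problem.  Subjects with any missing covariate are
excluded with a warning; no imputation is attempted because no defensible
imputation rule exists for this design.  Every retained subject must have at
least one observed relapse (the inclusion criterion of the emulated study).

## Model

Conditional on a subject's frailty ν and covariates x, the hazard of the
k-th gap is Weibull-proportional-hazards with a per-prior-event multiplier:

    h(t | k, x, ν) = ν · α^(k−1) · exp(β₀ + x′β) · γ t^(γ−1),   t > 0.

Design choices that were genuinely open:

* **Event-dependence form.** The event-dependence parameter is defined as a
  multiplicative factor α per prior event on the conditional hazard —
  the simplest form in the conditional-frailty literature.  An alternative
  exp(η·(k−1)) with η unconstrained is algebraically the same model with
  η = log α; a dynamic frailty update would be a different model and is out
  of scope.  Generator and likelihood use the identical form, so recovery is
  internally consistent.
* **Baseline scale.** The baseline hazard γ t^(γ−1) has unit scale; the
  scale is carried by an intercept β₀ inside the exponential.  Fitting
  includes β₀ by default (otherwise the baseline scale is pinned to 1, which
  a covariate-only report leaves ambiguous); summaries exclude it by default.
* **Frailty distribution.** Gamma with mean 1 and variance θ — the standard
  identifiable choice, conjugate to this likelihood.  Log-normal frailty is
  out of scope.  Under gamma frailty the marginal per-subject likelihood is
  closed-form: with d observed events and frailty-free cumulative hazards
  B_k,

      log L = Σ_{δ=1} log b_k + log Γ(1/θ + d) − log Γ(1/θ)
              + d log θ − (1/θ + d) log(1 + θ Σ_k B_k),

  and the population survival of a single gap is S(t) = (1 + θB(t))^(−1/θ).
  Kendall's τ between two gaps sharing a frailty is θ/(θ+2); both identities
  are used as test oracles.
* **Age scaling.** Age enters in raw years so the age coefficient reads
  "per year of onset age".  This matters for interpretation: a coefficient
  of 0.072/year compounds to exp(1.55) ≈ 4.7 at the cohort's mean onset age,
  which the intercept absorbs.

Numerical policy: all likelihoods in log space; log(1 + θB) via `log1p`;
θ below 1e-8 routed to the degenerate (ν ≡ 1) branch; overflowing proposals
evaluate to −∞ and are rejected rather than propagated.

## Synthetic cohorts

The generator emulates the study conditions: n = 159 subjects; covariates
drawn independently from the reported marginals (84.28% male, onset age
normal(21.52, 6.84²) truncated to [10, 43], 19.59% married, 53.46% sudden
onset, 47.8% head injury, 6.29% family history); default generating
parameters equal to the reported posterior means (β = (0.072, 0.418, 0.710,
0.199, 0.285, 0.327), γ = 0.860, α = 2.785, θ = 0.206, β₀ = 0).

Gaps are drawn sequentially by inverse transform,
T = (E / (ν α^(k−1) e^{β₀+x′β}))^{1/γ} with E ~ Exp(1), until the follow-up
window closes (the final gap is truncated with δ = 0) or the event cap is
reached.  Per-subject follow-up windows are Uniform(156, 364) weeks — three
to seven years, echoing a 2003–2009 accrual-plus-follow-up design.  The
event cap defaults to 5, matching the reported relapse-count range (2–5+).
When the cap is reached, observation of further events simply stops and no
trailing censored record is written: under the generating parameters the
post-cap exposure would otherwise dominate each subject's cumulative hazard
while representing events deliberately not modeled, which would distort the
likelihood rather than inform it.  Subjects who end a window with zero
observed events are resampled (fresh frailty and gaps, same covariates and
window) to enforce the ≥1-relapse inclusion rule; this mimics the study's
selection and induces the same mild selection effect on θ that the real
design would.

What the generator does *not* emulate: hospital length-of-stay (excluded
from the time scale by construction), covariate correlation (only marginals
are reported), calendar-time effects, or measurement error in admission
dates.  Passing recovery tests therefore show that the estimation machinery
is correct under the model's own assumptions — not that the model is
correct for any particular hospital's records.

A note on time scales: at the default generating parameters the linear
predictor is large at typical covariate values, so simulated gaps are much
shorter than clinical relapse intervals.  This is a direct consequence of
taking the reported covariate-scale coefficients at face value with a unit
baseline scale (the report pins down no intercept).  It is immaterial for
parameter recovery — the model is scale-equivariant and the likelihood is
evaluated in log time — but simulated datasets should not be read as
clinically realistic trajectories.

## Estimation

Metropolis-within-Gibbs, one sweep per iteration:

1. **(β₀, β, log γ, log α)** — one joint random-walk Metropolis block
   against the *frailty-marginalized* likelihood given θ.  This is a
   partially collapsed update: because the frailties are redrawn from their
   exact full conditional immediately afterwards, the composition leaves the
   joint posterior invariant, and the block does not drag against the
   current frailty draw.  (With the block conditioned on ν instead,
   coefficients of rare covariates — family history has ~10 carriers per
   cohort — mix an order of magnitude slower.)
2. **Frailties** — conjugate Gibbs: ν_i ~ Gamma(1/θ + d_i, 1/θ + Σ_k B_ik).
3. **log θ** — random-walk Metropolis on its full conditional given the
   frailties (inverse-gamma prior on θ, with the log-scale Jacobian).

Internally the block works in exactly reparameterized coordinates:
covariates, event rank − 1 and log gap time are centered, with the shifts
absorbed into the intercept (a unit-Jacobian linear bijection).  On the raw
scales the intercept, age coefficient, γ and α are near-collinear (raw age
and uncentered log t both act as near-constant offsets), which cripples any
random-walk kernel.  Chains are initialized at the BFGS MAP of the block
with the inverse Hessian as initial proposal covariance, then jittered per
chain; during burn-in the proposal covariance is re-estimated from the
chain history (Haario-style) and a Robbins–Monro rule tunes the global scale
to ≈25% acceptance (≈35% for the scalar θ walk).  All adaptation freezes at
the end of burn-in, so the retained draws come from a fixed, detailed-
balance-respecting kernel.

Defaults: 4 chains × 6000 iterations, 2000 burn-in, no thinning — at
n = 159 subjects this yields split-R̂ ≤ 1.05 and bulk ESS of a few hundred
per parameter in a few seconds on one CPU.  Priors (unreported in the
emulated analysis; these are deliberately vague, proper, WinBUGS-era
conventions, surfaced in `PriorSpec` rather than hidden): β_j ~ N(0, 1000);
log γ, log α ~ N(0, 100); θ ~ Inverse-Gamma(0.01, 0.01).  Note the IG(0.01,
0.01) prior has no finite moments; prior-recovery checks for θ therefore
compare quantiles, not means.

Summaries are posterior mean, sd, and equal-tailed 95% credible intervals
(matching the conventional presentation; not HPD).  A parameter is flagged
significant when its interval excludes the null value (0 for β and θ, 1 for
γ and α); no multiplicity adjustment is applied across the six covariates,
mirroring the emulated report, and the output says so.  Diagnostics
(split-R̂, bulk ESS) are computed with ArviZ; R̂ is omitted for single-chain
runs.

A second, independent route — `run_mcmc_marginal`, a joint MH sampler on
(β₀, β, log γ, log α, log θ) against the fully marginal likelihood with no
latent variables — targets the same posterior and serves as a
cross-implementation check in the test suite.

## Problem sizes used in the checks

Test and verification sizes were chosen to make each check sharp at desk
scale: likelihood-vs-quadrature agreement on 50 random instances of ≤5
subjects × ≤4 events (tolerance 1e-8); conjugacy and covariate-frequency
checks at 10⁵ draws; Kendall's-τ simulations at 10⁵ gap pairs (tolerance
0.01); the operating-point recovery at the study size n = 159 with the
default 4 × 6000 sampler; and the error-shrinkage comparison at n = 800 vs
n = 159 over 5 replicate seeds with 2 × 3000 chains, n = 800 being the
package's desk-scale stand-in for arbitrarily large cohorts.

## Known limitations

* Single recovery runs at n = 159 carry substantial realization noise:
  coefficients of low-information covariates (gender with 16% females,
  family history with 6% carriers) routinely land 1–2 posterior sds from the
  generating value, and θ is weakly identified at this size.  Recovery
  claims should be read against posterior sds, not as point reproduction.
* No semiparametric (Cox-type) baseline, no time-varying covariates, no
  competing risks, no model comparison (DIC/WAIC), no log-normal frailty.
* The generator draws covariates independently; any real covariate
  correlation structure is not represented.
* Calendar-date parsing is out of scope: admission histories must already be
  expressed as numeric week offsets from a common origin.
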
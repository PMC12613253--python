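# Methods

## Data model and preparation

The unit of collection is a prompt: participant × day × slot (five slots,
09:00–21:00 at 3-hour intervals; slot position is ordinal, clock time is
not modelled). Each prompt carries 0–10 scores for 8 symptoms and 3
exposures, an activity category (physical, cognitive, social, self-care,
rest, sleep) and its 0–10 effort. Rows with out-of-range scores, unknown
categories, or duplicate (participant, day, slot) keys are rejected with
logged reasons; conflicting covariate rows for one participant are a hard
error. Employment is collapsed to full-time / part-time / other at read
time, matching the model's adjustment set.

Day-level values are arithmetic means of non-missing slot scores; a day
value is missing only when all five slots are missing. Per-activity daily
effort is the mean over slots reporting that activity, 0 on days the
activity never occurred (an occurrence indicator is retained alongside, so
"no activity" and "zero-effort activity" remain distinguishable).

Eligibility: days are partitioned into maximal runs of consecutive
*complete* days — every symptom and every exposure present after
collapsing. Incomplete days break runs. All runs of ≥ 7 days are retained
(a participant can contribute several, one per assessment block); AR terms
never cross run boundaries. `min_days < 3` is rejected because a lag-2
model needs two conditioning days plus at least one likelihood day.

Grand-mean centering subtracts the mean over all retained day rows
(day-varying variables) or over participants (participant-level
variables); the constants are stored so effects map back to the raw 0–10
scale. Binary/dummy covariates are left on their 0/1 coding.

## The model

For participant *i*, day *t* (from the third day of each run), symptom *k*:

y_itk = x_it'β_k + ρ_k (y_{i,t−1,k} − ȳ_k) + u_ik + ε_itk, ε_it ~ N_K(0, Σ)

* The AR(1) term is a lagged-response (transition) formulation, with the
  lagged value centered at the symptom's grand mean, rather than residual
  autocorrelation. Both readings are defensible for this model family; the
  transition form keeps every full conditional conjugate and matches
  common practice in general-purpose MCMC engines.
* Exposures enter through restricted cubic splines at lags 0, 1, 2 with
  free coefficients per lag (no distributed-lag constraint linking lags —
  lag-specific effects are exactly what the reporting stage presents).
* Activity efforts at lags 0–2 are adjustment terms; same-day effort is
  included so same-day exposure effects are interpreted net of activity.
* Random intercepts are per participant × symptom and independent across
  symptoms; cross-symptom dependence is carried by the unstructured Σ
  (plus the AR term). Day-level random effects are intentionally absent —
  Σ absorbs within-day covariance.
* The first two days of each run are conditioned on, not modelled,
  avoiding any stationary-initial-distribution assumption.
* An optional binary effect modifier (sex, or preexisting mental-health
  condition) multiplies every exposure-spline column for subgroup
  analyses.

## Splines

Restricted (natural) cubic splines in the truncated-power
parameterisation: column 1 is x, nonlinear column j (knots t₁<…<t_k) is

[(x−t_j)₊³ − (x−t_{k−1})₊³ (t_k−t_j)/(t_k−t_{k−1}) + (x−t_k)₊³
(t_{k−1}−t_j)/(t_k−t_{k−1})] / (t_k−t₁)²

linear below t₁ and above t_k. Default 3 knots at the 10th/50th/90th
percentiles of the pooled day-level exposure distribution, shared across
symptoms and lags — the smallest basis with distinct linear and nonlinear
components; knot count and placement are configurable because no single
choice is canonical. Knots live on the raw 0–10 scale; the design columns
are the basis referenced at the exposure grand mean, s(x) − s(x̄), so the
model intercept is the expected severity at average exposure and effect
curves are exactly zero at the grand mean. Nonlinear truncated-power
columns are invariant to a common shift of x and knots, so centering does
not change them.

## Priors and sampler

Priors (all configurable): coefficients N(0, 10²); intercept N(5, 10²)
centred mid-scale; τ_k half-normal(5); Σ inverse-Wishart(K+2, I);
ρ_k uniform(−1, 1). These are weakly informative on a 0–10 outcome scale.

Gibbs sweep: (1) optional imputation of missing day-level outcomes from
their Gaussian full conditional, combining the same-day cross-symptom
conditional (via W = Σ⁻¹) and the next day's AR term — the
posterior-predictive step for data missing at random; (2) per symptom,
β_k from its multivariate-normal full conditional after reducing the
K-variate likelihood to the conditional of symptom k given the other
symptoms' current residuals, then ρ_k by an exact inverse-CDF draw from
its normal full conditional truncated to (−1, 1); (3) u_i from K-variate
normal full conditionals; (4) τ_k by stepping-out slice sampling (the
half-normal prior on the sd is not conjugate); (5) Σ from
inverse-Wishart(K + 2 + n, I + E'E). Non-finite states abort with an
error. Chains run sequentially from seeds spawned off the master seed;
every output is bit-reproducible given the seed. Defaults: 4 chains ×
5000 iterations, half burn-in, no thinning. Initial states are ridge
least-squares estimates plus noise, for overdispersed starts.

Reduced models (single symptom, no AR, no random effects, fixed Σ) make
the sampler draw independently from the exact normal posterior; this is
verified against the closed form and against OLS at vague priors.

Convergence: rank-normalized split R-hat and bulk ESS (via arviz) per
parameter, flagging R-hat > 1.05; at least two chains required.

## From draws to reported quantities

* **Effect curves.** Δ(g) = [s(g) − s(x̄)]'β per draw; point estimate =
  posterior mean, bounds = 2.5/97.5 percentiles. Grids default to
  [0, 99th centile of observed exposure] — the same presentation
  truncation used for published curves.
* **Joint p-values.** For the linear+nonlinear block with posterior mean m
  and posterior covariance V, W = m'V⁻¹m is referred to χ² with
  block-dimension df. This Wald-type bridge is the standard route from a
  Bayesian fit to the frequentist-style p-values such studies tabulate; at
  vague priors the posterior is asymptotically the sampling distribution
  of the MLE, which is what makes the bridge calibrate (verified by the
  null-replicate experiment). A two-sided posterior tail probability for
  the 1-df linear-only contrast is provided as the Bayesian alternative.
  Raw p-values, no multiplicity correction — the pipeline's reporting is
  hypothesis-generating by design.
* **ICC.** Design-based one-way ANOVA moment estimator on day-level
  scores, (MSB − MSW)/(MSB + (n₀−1) MSW); computable before any model
  fit, as a cohort description.
* **Subgroup tests.** Joint Wald-type test over the modifier × spline
  interaction block, plus per-stratum curves (reference: modifier 0;
  index: modifier 1).

## Synthetic cohorts

Generation is day-level-first, mirroring the model: latent per-exposure
AR(1) processes with participant random means; symptom day means =
intercept + random intercept + ρ·(previous-day deviation) + distributed-lag
effects + covariate effects + multivariate residual; prompt scores are the
day value plus slot noise, clipped to [0, 10]; missingness (per-variable
prompt level, optional whole-day) is applied last and is MAR by
construction. With slot noise and missingness off, day aggregation
recovers the latent process to machine precision.

Defaults emulate the published cohort: 155 participants, three 8-day
blocks, 74% female, mean age 48 (sd 12), 17% with a preexisting
mental-health condition, exposure means 2.1/2.0/1.3 (stress/worry/
rumination), symptom means from the descriptive table (fatigue 5.4 the
highest), ρ = 0.35, τ = 1.2, residual sd 0.9 with 0.3 cross-symptom
correlation, slot noise 0.8, 5% prompt and 2% day missingness. A handful
of true effects are switched on, including one deliberately nonlinear
stress → fatigue dose-response so the spline machinery is exercised;
covariate effects default to zero so each recovery experiment can switch
on exactly what it tests.

True effects are parameterised as a linear slope plus optional nonlinear
rcs coefficients with explicit knots; `ground_truth` maps them onto the
fitted model's parameter names, exactly when the truth is linear (nonlinear
entries 0) or when the model is given the same knots, and refuses
otherwise.

**Boundary censoring and the calibration regime.** Real severity scores
pile up at 0; the realistic defaults reproduce that (e.g. ~12% of latent
stress days at the floor). A Gaussian model is then not the exact
generative process, and local dose-response slopes near the floor are
genuinely attenuated — the rcs linear coefficient is the slope *below the
first knot*, exactly where censored days concentrate. Experiments that
compare estimates against ground truth therefore use
`calibration_config`: all exposures and symptoms centred mid-scale
(mean 5, modest variances), making boundary contact negligible (~0.03% of
days) so every generator parameter is exactly the model's estimand.
Consequence: passing recovery/coverage tests demonstrate the correctness
of the sampler and the reporting algebra, not robustness to floor
effects, ordinal measurement, circadian structure, or informative
missingness — none of which the generator emulates.

## Experiment sizes and numerical choices

Validation experiments are scaled to desk hardware: conjugate oracle
(150 × 5, 4 chains × 2000); recovery (60 participants × 14 days, full
default model, 2 chains × 2000, truth: stress→fatigue 0.5, ρ 0.3, τ 1,
Σ = I); coverage (50 replicates of 20 × 10 days, 2 chains × 1500, a
3-symptom model); null calibration (200 replicates of 15 × 10 days,
2 symptoms, 2 chains × 600). The acceptance band for coverage is
[85%, 99%] and for the null rejection rate the exact binomial 95% band
around 5%.

Numerics: posterior draws from precision matrices via Cholesky;
near-singular posterior covariance in a joint test raises an error
(suggesting longer chains) rather than returning a spurious p-value; the
truncated-normal draw for ρ falls back to pinning at the nearer bound if
the interval mass underflows; empty participants draw their random
intercept from the prior. CSV round-trips use 17-significant-digit
formatting and round-trip float parsing, which makes the
simulate → prepare → fit → report pipeline byte-reproducible.

## Known limitations

* P-values are a Wald bridge from posterior moments, not exact
  finite-sample tests; their calibration is demonstrated empirically at
  the experiment sizes above.
* The Gaussian likelihood ignores the bounded, semi-ordinal nature of
  0–10 scores; with heavy floor effects, effects near the floor are
  attenuated relative to the latent scale (quantified above).
* The generator does not emulate compliance-window dynamics, circadian
  within-day variation, dropout, or not-missing-at-random mechanisms.
* Missing-outcome imputation is opt-in and exercised lightly; the default
  pipeline guarantees complete outcomes by construction (day collapsing
  plus the eligibility filter), so the flag matters only for bespoke
  datasets.
* Model comparison (WAIC/LOO) and non-Gaussian likelihoods are out of
  scope.
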
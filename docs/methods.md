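# Methods

This note documents the models implemented in `emcog`, the assumptions
behind the virtual-respondent generator, the numerical choices made
where the underlying testing platform leaves details open, and what the
package's validation does and does not establish.

## Test engines

Each engine is a pure state machine over a seeded RNG: stimulus
generation, adjudication, scoring, and termination are deterministic
given the session seed and the responder's answers. Stimulus
randomness and (simulated) behaviour use separate RNG streams so either
can be held fixed. Correctness is never stored as an unexplained flag:
`adjudicate(test_id, stimulus, response)` re-derives it from the raw
records, and `rescore_session` folds the scoring rule over a stored
log, which the test suite verifies against the engine-emitted score on
thousands of random sessions.

Decisions taken where the platform's published description is silent:

- **Matching Pair grid progression.** The grid "gradually increases"
  from 2×2 to 4×4; we advance one step along a configurable ladder
  (default 2×2, 2×3, 3×3, 3×4, 4×4) per *correct* trial, hold at the
  maximum, and never shrink on errors. This matches the documented 3×3
  worked example and the stated bounds. The session's running score
  starts at 0.
- **Memory Matrix error limit.** "Three incorrect responses" is read as
  three *cumulative* (not consecutive) errors. Adjudication of a
  multi-tile reproduction is all-or-nothing: the selected set must
  equal the target set; off-grid taps are simply incorrect, not errors.
- **Memory Matrix span→grid mapping.** The published description does
  not bind the highlighted-tile count to the grid side. We use the
  smallest side g with g² ≥ 2·span (capped at 7), which keeps the
  highlighted density at or below 50% at every span.
- **Termination guard.** Under a literal 3-error rule a perfect
  responder would never finish Memory Matrix or CopyKat, so both carry
  a `max_trials` guard (default 100) reported as `terminated_by =
  "trial_count"`.
- **Timeout boundaries.** Responses landing exactly on a timeout
  boundary (2 s for Quick Tap, 20 s for CopyKat) count as in time
  (closed interval). Premature Quick Tap taps end the trial and score
  as incorrect; they contribute no latency to the mean-RT score, which
  averages *correct* trials only and is flagged missing (NaN) when
  there are none.
- **CopyKat error handling.** After an error the *identical* sequence
  (same tiles, same order) is re-presented; correct trials append one
  uniformly drawn tile.
- **List-memory materials.** Word lists are synthetic pronounceable
  tokens generated deterministically from the list id, serving as
  alternate forms; list norming is out of scope. The forgetting outcome
  is short-delay minus long-delay recognition score for the same day's
  list (negative = words gained).

## Protocol scheduler

Three notification windows per day are placed by splitting the wake
span (default 08:00–22:00; minimum 8 h) into equal tertiles, drawing a
seeded uniform time inside each, and repairing forward to maintain the
2-hour minimum gap; links expire 60 minutes after notification. Test
assignment follows a counterbalanced day×window grid under which each
non-VLMT test is administered exactly 9 times over 14 days and the
list-memory study+recognition runs daily. On dual-recognition days the
recognition window matching the study window is the short delay and the
later window the long delay (8 long delays over the protocol). Within
a session the study list comes first and the short-delay recognition
last, so intervening tests act as the distractor; the inhibition tap
task always immediately follows the simple tap task. A validator
re-checks every invariant and names each violated rule.

## Virtual respondents

The generator's defaults are the study conditions the pipeline is meant
to handle: two groups of 45 (patients) and 21 (volunteers), 14 days × 3
sessions.

- **Missingness** is simulated at session level:
  P(miss) = logistic(β₀ᵢ + 0.093·day), with person intercepts
  β₀ᵢ ~ N(−1.692, 0.9²). The slope is the fatigue effect the analysis
  refits; the intercept mean is set so the *expected* adherence equals
  69.7% (computed in closed form under the intercept distribution). A
  long-delay recognition whose study session was missed is itself
  unadministrable and is recorded as missing.
- **Accuracy** is per-trial Bernoulli with
  p = logistic(base + w·abilityᵢ + practiceᵢ·day − demand), where
  `demand` is a fixed difficulty ladder (proportional to span for
  Memory Matrix, to sequence length for CopyKat, constant for the
  others) so adaptive tests equilibrate at ability-dependent spans.
  Group ability gaps default to the observed standardized effect sizes
  per test (0.25–0.54).
- **Reaction times** are lognormal with person/test-specific location,
  a slow practice speedup, and a within-person dispersion 30% wider in
  the patient group (the intraindividual-variability contrast).
- **Lapses** (probability 0.02) yield an incorrect response on every
  test — a non-response on tap/sequence tasks and a wrong answer on
  forced-choice items — so `lapse_prob = 1` produces floor scores, a
  degenerate case the tests exercise.

Because practice enters trial accuracy on the logit scale, the induced
session-score-vs-day slope has no closed form. Parameter-recovery
checks of the practice and changepoint *fitters* therefore use
`simulate_score_trajectories`, which draws session scores directly from
the linear mixed model being fit (configurable per-group slopes,
optional piecewise trend); fatigue recovery uses the session-level
missingness mechanism, which is exactly the fitted logistic model.
What passing recovery tests show is that the estimation machinery is
unbiased under its assumed model at study scale — not that real
ambulatory data satisfy those assumptions. The generator also omits
circadian/mood dynamics, device effects, and item-difficulty
heterogeneity, so simulation results should not be read as empirical
psychometrics of any real platform.

## Statistical models

- **Fatigue.** `missed ~ day + (1 | participant)`, binomial-logit,
  fit by adaptive Gauss–Hermite maximum likelihood (`emcog.glmm`):
  nodes are centred at each cluster's posterior mode with Laplace
  scaling (25 nodes by default), fixed effects optimized by BFGS, Wald
  SEs from the numerical Hessian. The fitter reproduces `lme4::glmer`
  (nAGQ = 25) estimates to ~5 decimals on shared test data and is
  checked in-suite against brute-force numerical integration. Constant
  outcomes raise a separation flag instead of an estimate. The model
  can be fit at test level (default; every scheduled administration) or
  session level.
- **Practice.** `score ~ day × group` with participant random effects;
  Gaussian via statsmodels `MixedLM` (ML, not REML), except the
  count-scored Odd One Out total, which uses the Poisson GLMM. If the
  day×group interaction is not significant at p < .05, group and the
  interaction are removed and the pooled day slope reported; otherwise
  within-group slopes come from per-group refits. A random day slope is
  attempted when there are ≥ 5 observations per participant and kept
  only if the fit converges non-singularly. No multiple-testing
  adjustment is applied (p-values are reported unadjusted).
- **Stabilization day.** For candidate knots k = 2…13 the model uses
  the continuous basis s₁ = min(day, k), s₂ = max(day − k, 0) with a
  random intercept; the knot minimizing ML-AIC is selected (the
  selection criterion is our choice; none is prescribed). If no knot
  improves on the plain linear fit, a linear sentinel (`knot_day =
  None`) is returned. "Stabilized" means the post-knot slope is not
  significant at .05.
- **MSSD.** Σ(xᵢ₊₁ − xᵢ)²/(2(n−1)) over chronologically ordered
  completed sessions. The denominator is read as 2(n−1) — the standard
  successive-difference statistic — rather than the nonstandard 2n−1.
  Missing sessions are skipped, so surviving neighbours are treated as
  consecutive; no gap weighting is applied by default.
- **ICC.** One-way random-effects ICC(1) = (MSB − MSW)/(MSB +
  (k₀ − 1)·MSW) with the unbalanced-design cluster size
  k₀ = (N − Σkᵢ²/N)/(n − 1). Negative values (within-person variance
  dominating) are returned untruncated so degenerate reliability is
  visible; degenerate variance yields NaN.
- **Composite.** Per-participant mean scores are transformed by the
  fixed skew lists (log: CopyKat time, Odd One Out time, Quick Tap 1
  time, CopyKat total; square: Matching Pair, Memory Matrix, VLMT; the
  ceiling-affected Odd One Out total and Quick Tap 2 are excluded),
  standardized to sample Z-scores, time variables negated so higher is
  better, and averaged over available variables. The fixed lists (not
  re-estimated skewness) are the default for reproducibility of the
  construction.
- **Group comparisons.** Levene's test gates pooled-variance vs Welch
  t-tests; Cohen's d always uses the pooled SD. Validity is Pearson r
  per (mobile aggregate, battery score) pair within group; cells with
  fewer than 3 complete pairs are left missing.

## Problem sizes used in validation

The test suite validates at sizes chosen to be statistically
informative while keeping the default run fast: 1000 random sessions
for the log→score round trip; 100 Monte-Carlo replicates at full study
scale (66 × 42 sessions) for fatigue-slope recovery; 100 replicates of
66 × 14 score trajectories for practice-slope recovery; 25 replicates
for changepoint recovery; 200 sessions for the chance-level recognition
check. Recovery is asserted as |mean estimate − truth| within twice
the Monte-Carlo standard error.

## Known limitations

- The engines model test logic, not presentation: no graphics, audio,
  touch latency, or device/OS timing differences.
- The Gaussian mixed models support random intercept (+ optional day
  slope) only; richer covariance structures are out of scope.
- Scores are raw engine scores; published summary tables for some tests
  appear to use a rescaled metric that is not specified, so absolute
  score levels are not comparable across sources — within-toolkit
  analyses are unaffected.
- ICC variant choice (one-way random effects) is a documented
  convention; other variants (e.g. two-way consistency) would give
  different values.
- Clinical-scale scoring, demographic norming/T-scores, and effort or
  cheating detection are not implemented.
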
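# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the `gazeconf` pipeline.

## Task structure and time conventions

A trial presents two option images left and right of screen centre
(Stimulus-On, 4 s by default, 2 s in the short-observation variant), removes
them at a GO signal leaving empty frames (Stimulus-Off), and accepts a
left/right button press within a 4 s response window. Four ratings on a
0–10 scale follow: confidence (C), reward (R), interest (I), complexity (CM).
Variants: LAS keeps the images visible throughout (its post-GO intervals map
onto the same SOffUD/SOffPD names), rLAN swaps button and image side, sLAN
halves the Stimulus-On duration.

All trial clocks start at stimulus onset; intervals are half-open
`[start, end)` in milliseconds. The pre-stimulus fixation and context phases
are represented in `TrialTimeline` but carry no gaze: no analysis in scope
reads pre-stimulus gaze. Analysis intervals: `SOn = [0, GO)`,
`SOffUD = [GO, decision)`, `SOffPD = [decision, GO + 4 s)`; non-response
trials get a full-window SOffUD and an empty SOffPD, and are excluded anyway
by the response-time rule (negative, above 4 s — strictly greater than
4000 ms — or absent).

## Dwell extraction

A dwell is a maximal run of valid samples inside one AOI, tolerating internal
gaps up to `max_gap_ms` (default 80 ms — blinks and single dropped samples)
and discarding runs shorter than `min_dwell_ms` (default 100 ms, a
conventional minimal fixation). Neither criterion is dictated by the paradigm,
so both are exposed. AOIs default to the 265×256 px image frames padded by
25 px, centred at (480, 540) and (1440, 540) on a 1920×1080 screen: the image
and the empty frame that replaces it count as the same target region. A
dwell's end is its last sample time plus one sample period. A change of
target (CoT) is a pair of adjacent dwells on different sides, counted in the
interval where the second dwell begins; fCoT divides the count by the
interval length in seconds. The log observation-time ratio uses
`log((T_R + ε)/(T_L + ε))` with ε equal to one sample period (the smallest
measurable dwell), so empty dwells never produce infinities.

## Psychometric fit and permutation significance

Per participant and interval, trials are rank-split into four equal-count
bins of the log time ratio (remainder to the lower bins; the bin
representative is the within-bin median, which is robust to extreme ratios —
the loss and the representative are config options since neither is uniquely
determined by the procedure's description). The two-parameter logistic is
fitted to the four (proportion, count) points by binomial maximum likelihood
with a damped Newton iteration; the problem is convex, so the fit is
deterministic. Complete separation is reported by capping the slope at a
configurable `beta1_max` (default 20) and flagging the fit.

Significance per participant: the four (p, n) pairs are shuffled across the
four bin positions 10,000 times, the slope is refitted, and the observed
slope must exceed the 95th percentile of the shuffle distribution. Four
points admit only 24 orderings, so each ordering is fitted once and the
shuffles index into the 24 fits — exactly equivalent to refitting every
shuffle, since the refit is deterministic given the ordering. An exact
enumeration mode weights the 24 orderings equally. The reported
`perm_p = (1 + #{β₁,shuffle ≥ β₁,obs}) / (n_shuffles + 1)` never reaches
zero. Because the null distribution is discrete over 24 orderings the test is
conservative: its null rejection rate is at most ~1/24 ≈ 0.042, below the
nominal 0.05 (measured by the acceptance script on 2,000 simulated null
participants).

Group tests are one-sample/two-sample t-tests; each is accompanied by the
JZS Bayes factor for the null (Cauchy prior on the standardized effect,
default scale √2/2, computed by adaptive quadrature split at the likelihood
peak). In the motor-reversed variant the psychometric response is the
probability of pressing the *right button*, which makes the expected slope
negative there.

## Cognitive-factor GLMs

Per participant and interval, OLS of (a) the selected-option observation-time
fraction on z-scored C, R, I, CM plus the pairwise products R×I, R×CM, I×CM
of the z-scores (8 coefficients), and (b) the z-scored #CoT or fCoT on
z-scored C, R, I, CM (5 coefficients). The fraction response is left on its
natural proportion scale (the alternation responses are z-scored as stated
for them); interactions are products of z-scored main effects. z-scores use
the n−1 denominator within participant. Group inference is the two-stage
summary-statistics approach: a one-sample t-test of each coefficient across
participants, uncorrected (a Benjamini–Hochberg option exists but is off, to
match the uncorrected reporting convention). Participants with too few trials
(12 for the 8-parameter design, 8 for the 5-parameter one) or rank-deficient
designs are reported and dropped from the group stage, not silently ignored.

## Diffusion models and confidence readouts

Evidence `x(t)` accumulates from 0 by Euler–Maruyama steps
`x ← x + μ·dt + σ·√dt·N(0,1)` (default dt = 1 ms, horizon 8 s) until
`|x| ≥ θ`. The parallel account uses the constant drift μ = μ₁ − μ₂; the
sequential account uses +μ₁ while option 1 is attended and −μ₂ while option 2
is (zero during saccade gaps). Choice and decision time come from the first
crossing; runs that never cross within the horizon yield no choice. A warning
is raised when the step is coarse relative to (θ/σ)², where discretization
biases first-passage estimates. The simulators are validated against the
closed forms P(upper) = 1/(1+exp(−2μθ/σ²)) and the zero-drift mean first
passage θ²/σ².

Confidence readouts: parallel `g(t) = Φ(θ/(σ√t))` — the accumulated-noise
scale is taken as σ√t, the standard diffusion result, since the σ(t) in the
source derivation is typeset ambiguously; a linear σ·t variant is exposed as
an option. Sequential: `g = 1/(1+exp(−2μ₀(Δt₁−Δt₂)/σ²))`, used literally with
the small-value approximation Δxᵢ ≈ μ₀tᵢ (the companion assumption
μ₁ = μ₀/2 differs from it by a factor of two; the printed readout is
followed). The three observation models (parallel, sequential, hybrid — see
README) are referred to by name everywhere, never by index, because the
published numbering of the three models is internally inconsistent.

## Model inversion and random-effects selection

The confidence report, normalized to [0, 1], is regressed on the model's
predictors: intercept, (Δt₁−Δt₂) in seconds, and/or 1/(Δt₁+Δt₂) in 1/s,
where Δt₁/Δt₂ are the dwell times on the selected / non-selected AOI summed
over SOn + SOffUD — the evidence-gathering span up to commitment (the span is
configurable; the original description does not pin it down). Trials with
zero total observation time are dropped from designs with an inverse-time
term.

These are linear-Gaussian models, so the log model evidence is computed in
closed form instead of by a variational scheme (the bound is tight in the
conjugate case): a zero-mean Gaussian prior on the coefficients
(`prior_sd_alpha = 5` on per-participant-standardized predictors, so the
scale means the same thing across models) with either a fixed noise SD or the
conjugate inverse-gamma noise prior (a = b = 10⁻³; the default). The
quadrature-oracle test pins the closed form to a dense-grid integration on a
toy problem. Posterior coefficient means and covariances are returned on the
original predictor scale.

The participants × models evidence matrix feeds the standard random-effects
update: `u_nk ∝ exp(F_nk + ψ(α_k) − ψ(Σα))`, `α = α₀ + Σ_n u_n`, iterated to
`max|Δα| < 10⁻⁶` (cap 10⁴ iterations), with Dirichlet prior α₀ = (1,1,1).
Model frequency is the Dirichlet mean α_k/Σα; exceedance probabilities are
estimated from 10⁶ seeded Dirichlet draws. Only within-participant evidence
differences matter (row-shift invariance, tested). Note the frequency of a
unanimous winner is bounded by (N+1)/(N+3) under the unit prior — 0.913 at
N = 20 — so expected frequencies never literally reach 1.0 at cohort sizes
like these.

## The synthetic-experiment generator

The generator exists so that every downstream stage has data with the
statistical structure the analyses assume, and so that model recovery can be
demonstrated. Per trial:

1. Option values μ₁, μ₂ ~ N(0.15, 0.1²) truncated at 0 (1/s). Positive
   values make attention informative: attending an option pushes the
   accumulator toward it, which produces the looking-time/choice coupling the
   psychometric stage measures.
2. An alternating dwell schedule with gamma dwell durations (shape 4, mean
   730 ms — calibrated so Stimulus-On alternation runs at ~1.3 Hz), 40 ms
   saccade gaps of invalid samples between dwells (so dwell extraction is
   exercised against gaps), first side random.
3. A bounded diffusion (σ = 0.5, θ = 1, so the zero-drift mean first passage
   is 4 s and most commitments land near the GO) — gated by the schedule for
   the hybrid and sequential cohorts, constant-drift for the parallel cohort.
   The press follows commitment after a motor latency ~N(300, 50²) ms
   (floor 50 ms), no earlier than the GO; presses beyond the response window
   become non-response trials.
4. After commitment, gaze partially disengages while the images are still
   visible (each remaining pre-GO dwell is redirected off-AOI with
   probability 0.5 — visible stimuli keep attracting fixations) and fully
   disengages to screen centre from the GO (or commitment, if later) until
   the press; alternation resumes after the press, the double-checking
   phase. This yields the characteristic drop of #CoT during SOffUD and its
   rebound during SOffPD, and gives the total observation time genuine
   trial-to-trial variance tied to deliberation time — which is exactly what
   the 1/(Δt₁+Δt₂) confidence term means.
5. True confidence comes from the configured observation model applied to the
   in-AOI dwell times up to the press (defaults α₀ = 0.5, α₁ = 0.15 /s,
   α₂ = 0.3 s), clipped to [0, 1]; the reported C adds Gaussian noise
   (sd 0.05) before rounding to the 0–10 scale. R, I and CM are drawn with
   fixed weak correlations to the trial-difficulty latent −|μ₁−μ₂|
   (complexity up, reward down, interest slightly up with difficulty).
6. Gaze samples at 60 Hz (EyeTribe-class hardware; configurable): AOI centre
   plus isotropic 25 px Gaussian jitter during dwells, screen centre during
   off-AOI segments, invalid samples during saccade gaps.

Ratings use the 0–10 scale (the procedure text also mentions 0–9;
`rating_scale_max` accepts both). The motor-reversed variant is simulated as
the identical gaze/decision process with the button flipped. Ground truth
(per-trial Δt₁, Δt₂, true confidence, drifts, the generating α) is emitted in
a separate table so analysis code can never read it by accident.

What the generator does **not** emulate: saccade kinematics, microsaccades,
smooth pursuit, blinks beyond validity flags, pupil dynamics, calibration
drift, any semantic content of the contexts and images, value learning across
trials, or lapses/biases in the ratings beyond Gaussian noise. Passing tests
therefore certify the *pipeline* — that it measures what the generative
process put in, at realistic sizes and noise levels — not that real gaze data
satisfy the models' assumptions.

## Numerical and degenerate-input choices

* Logistic fits: damped Newton, 60 iterations, slope clipped to ±20,
  intercept to ±30; ties in permutation comparisons use a 10⁻¹² epsilon.
* Dwell ordering checks tolerate 10⁻⁶ ms of floating-point fuzz; sample-run
  merging tolerates one sample period plus the configured gap.
* Zero-length intervals yield NaN metrics, never division errors; zero
  variance in a rating factor or correlation variable raises or skips with a
  named message.
* The JZS quadrature splits the integral at the likelihood peak so extreme t
  statistics cannot hide the mass from the integrator; it raises if the
  accumulated quadrature error exceeds 0.1% of the integral.
* The RFX update subtracts row maxima before exponentiation; exceedance
  sampling uses one seeded generator, making every selection result
  reproducible.
* A single pipeline seed expands into per-stage seed sequences keyed by
  (seed, stage index), so stages can be re-run in isolation.

## Problem sizes

The validation suites run at the study's own scale: cohorts of 8–24
participants × 80 trials for recovery and selection (the acceptance script
uses 20 × 80), 2,000 simulated participants for the permutation-test
calibration, and 10³–10⁴ Monte-Carlo runs against the first-passage closed
forms. These sizes make every stochastic check decisive at the asserted
tolerances while keeping the whole suite fast.

## Known limitations

* The two-stage (per-participant fit, then group t-test) inference ignores
  per-participant estimation uncertainty; no hierarchical variants are
  provided.
* The psychometric model has no lapse/guess parameters, so floor/ceiling
  choice behaviour maps onto extreme slopes (capped and flagged).
* The conjugate evidence assumes Gaussian residuals for a bounded, discrete
  rating; with 11 response levels this is a reasonable approximation but it
  is an approximation.
* Exceedance probabilities are Monte-Carlo estimates; at 10⁶ draws their
  standard error is below 10⁻³.
* The generator's post-commitment disengagement parameter (0.5) is a
  behavioural assumption, not an estimated quantity; analyses that depend on
  the variance of total observation time are sensitive to it.
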
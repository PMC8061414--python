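# Methods

`facepriors` implements a computational-psychiatry analysis pipeline that
relates psychosis proneness in the general population to visual priors for
socially meaningful stimuli.  Two behavioural measurements feed a rank-based
correlation layer: a per-participant *face-detection prior* estimated from a
detection-in-noise task with a Bayesian observer model, and a
*direct-gaze bias* from a breaking continuous-flash-suppression (bCFS) task.
Because no participant data ship with the package, a synthetic-cohort
generator reproduces the study conditions so every stage can be exercised
and validated end to end.

## The Bayesian observer model

On each face-task trial the participant sees either a noise image or a noise
image with an embedded face and reports "face" or "no face".  The observer
holds a prior probability π ∈ [0, 1] that a face is present and receives a
binary sensory likelihood governed by a sensitivity parameter s ∈ [0, 1]:
the likelihood of "face" is s when a face is embedded and 1 − s otherwise.
The probability of a "face detected" response is the two-hypothesis
posterior

    P(detect) = πL / (πL + (1 − π)(1 − L)),   L = s·face + (1 − s)(1 − face),

and the response log-likelihood Σᵢ [dᵢ ln Pᵢ + (1 − dᵢ) ln(1 − Pᵢ)] is
maximised per participant over (π, s) ∈ [0, 1]² by a bounded Powell search
with five starts (the four corners and the centre; ties broken by higher
log-likelihood, then smaller π).  Probabilities are clipped to
[1e-9, 1 − 1e-9] before logarithms.

**Identifiability and the closed-form oracle.**  The model is saturated:
its two parameters are in bijection with the two sufficient statistics, the
hit rate h and false-alarm rate f.  Writing odds(x) = x/(1 − x), the
maximum-likelihood solution for interior rates is

    odds(π) = sqrt(odds(h)·odds(f)),   odds(s) = sqrt(odds(h)/odds(f)).

This algebraic solution is used throughout the tests as an independent
oracle for the numeric fit (agreement to 1e-4 is asserted over 1000 random
interior datasets, together with a 200 × 200 grid-search cross-check).

**Boundary data.**  When h or f is exactly 0 or 1 the MLE does not exist:
the likelihood supremum is approached at a corner of the parameter square,
so any numeric "optimum" there is an artifact of the clipping constant.
Such datasets are fitted after the log-linear correction (add 0.5 to each
response cell and 1 to each denominator — the same correction used for the
signal-detection summaries) and flagged `boundary_corrected`.  This keeps
the estimator well defined and ε-independent; at the study's 40/60 trial
counts boundary datasets arise for roughly 0.7% of simulated observers, and
the corner artifacts they would otherwise produce (|error| ≈ 0.3 in π) are
large enough to dominate the tail of the recovery-error distribution.

Sensitivity below 0.5 (a worse-than-chance sensor) is allowed and flagged.
Standard signal-detection summaries (d′, criterion c, β = exp(c·d′), and
the nonparametric A′) are emitted alongside the model parameters.

## The bCFS direct-gaze bias

Each gaze-task trial shows a face with direct or averted gaze to one eye,
suppressed by a dynamic mask in the other, for at most 15 s; the
participant localises the face's quadrant as soon as it breaks through.
Analysis keeps response times of correctly localised trials only.
Participants with more than 65% missed trials (strict inequality) are
excluded; mislocalised responses count as responses for this rule — the
rule targets mask suppression, not localisation errors — but never enter
the RT means.  The per-participant statistic is

    direct_gaze_bias = mean RT(averted) − mean RT(direct),

positive when direct gaze reaches awareness faster.  (The opposite
subtraction direction is available by configuration.)  The group sanity
check is a one-sample t test of the biases against zero plus a JZS Bayes
factor.  Means are arithmetic on untransformed seconds; a median option
exists.

## Rank-based inference and Bayes factors

Questionnaire totals (PDI-21 delusion proneness, CAPS hallucination
proneness) are right-skewed and the gaze bias need not be normal, so all
six headline pairings (CAPS/PDI × face prior, sensitivity, gaze bias) use
Spearman correlations: Pearson correlation of mid-ranks, two-sided p from
the t approximation t = ρ√((n − 2)/(1 − ρ²)).  Observations are pairwise
complete, and gaze-excluded participants drop out of gaze pairings only.
A normal-vs-uniform AIC comparison (both two-parameter MLE fits) is
provided for distribution checks on the bias.

Bayes factors are reported as BF01 = P(D|H0)/P(D|H1) (values > 1 favour
"no effect") with Jeffreys-style labels: beyond 10 "strong", 3.2–10
"substantial", within [1/3.2, 3.2] "anecdotal"; band edges fall into the
weaker category.

* **Correlation BF** — stretched symmetric beta prior of width κ on ρ
  (κ = 1, the default, is uniform on [−1, 1]), evaluated by the closed-form
  Gaussian-hypergeometric expression, with adaptive quadrature of the exact
  sampling density of r as a fallback.  The tests check both routes against
  each other to 1e-6 relative error.
* **JZS t-test BF** — Cauchy(0, scale) prior on the standardised effect
  (default scale 0.707), evaluated by adaptive quadrature of the
  noncentral-t likelihood; cross-checked against the inverse-gamma
  g-mixture form.

The statistics package used for the original analysis does not document its
Bayes-factor priors, so printed Bayes factors are context rather than
targets; both prior widths are configurable.

## Stimulus synthesis

Face-in-noise stimuli follow a fixed three-stage degradation on a white
450 × 450 px canvas: (1) 1000 black circles with integer diameters uniform
on 1–15 px, centres uniform over the canvas (discs may clip at borders);
(2) multiplicative speckle noise J = I + nI with n zero-mean uniform of
variance 2, clipped to [0, 1]; (3) an isotropic Gaussian blur of kernel
variance 10 px² (σ = √10, reflective boundary), then a linear contrast map
onto [0.1, 0.9].  Of 100 stimuli, 40 targets receive a face blended in
between stages 2 and 3 at a uniform-random position fully inside the
canvas, cycling through 20 distinct identities.

Design points that were genuinely open:

* The source describes stage 3 both as a blur and by naming a
  noise-injection routine; the operative reading here is the blur, with an
  additive-Gaussian-noise mode retained as an option, and the variance read
  on the kernel (px²) scale.
* Face photographs are replaced by a procedural template (oval head, eyes,
  brows, nose, mouth, smooth shading) on an exactly-white background, so
  the default multiplicative blend leaves the surrounding noise untouched
  while circle noise visibly overlays the face; a replace-blend exists.
  The embedded face size, unstated in the source, defaults to 150 px.
* Coordinates are 0-based (row, col) from the top-left; intensities are
  floats in [0, 1]; 8-bit quantisation happens only at PNG export.

Every stage maps [0, 1] images to [0, 1] images, records itself in a
provenance list, and is deterministic given the seed; with circles,
speckle and blur disabled, a target stimulus equals the contrast-mapped
template exactly (an end-to-end identity used in the tests).

## The synthetic cohort generator

The generator encodes the study conditions as defaults and the study's
qualitative finding as programmable ground truth.  What it emulates, and
what it deliberately does not:

* **Questionnaire totals** are gamma distributed, moment-matched to cohort
  mean/SD (PDI 76.95/42.86, CAPS 106.90/48.81; both right-skewed by
  construction), clipped to instrument ranges (PDI ≤ 315, CAPS ≤ 480), and
  linked by a Gaussian copula (default rank coupling 0.6, a typical value
  for these instruments in general-population samples).  Item-level
  responses are not simulated.
* **Rank couplings** use a Gaussian copula whose latent correlation inverts
  the exact finite-n expectation of Spearman's rho for bivariate normal
  samples, E[r_s] = 6/(π(n+1))·((n−2)·asin(ρ/2) + asin(ρ)), so the
  realised rank correlation across replicate cohorts is centred on the
  configured value (verified to within 0.03 at coupling 0.5, n = 39).
* **Face prior** is a monotone map of a noisy rank blend of CAPS (default
  coupling 0.50) into the range [0.15, 0.75]; **sensitivity** is uniform on
  [0.60, 0.90], independent of symptoms.  Detection responses are Bernoulli
  draws from the observer model's own posterior — the analysis model is the
  forward model, so fitting is a well-posed recovery problem.  No
  trial-level structure beyond Bernoulli (no learning or fatigue) is
  invented.
* **Breakthrough times** are shifted lognormal (shift 0.2 s, trial-level SD
  1.5 s) with participant baselines Normal(4.055, 1.2) s for averted gaze
  and a per-participant direct-gaze advantage subtracted for direct gaze.
  The advantage has a uniform marginal with mean 0.67 s and half-width
  0.97 s, rank-coupled to CAPS (default 0.43).  Times beyond the 15 s
  ceiling and random lapses (default rate 0.08) become misses.  Two
  designed participants receive a 0.9 per-trial miss rate — participants
  for whom the mask "worked too well" — placing them far enough above the
  65% rule that their exclusion is a design property rather than a
  Binomial(48) coin flip.  Mask dynamics, contrast ramps and eye assignment
  are not modelled; behaviour is simulated at the response level.

Passing tests on these cohorts therefore demonstrate the pipeline's
correctness and calibration under the generative assumptions above; they do
not certify behaviour on real data with, e.g., sequential effects, RT
distributions with heavier tails, or questionnaire measurement error.

## Numerical choices and test design

* Probability clipping ε = 1e-9; Powell options xtol = 1e-8, ftol = 1e-12,
  five starts.  The optimiser's inner log-likelihood uses a scalar fast
  path (pure `math.log` arithmetic on the four sufficient counts), which is
  bit-compatible with the vectorised posterior used elsewhere and keeps the
  large oracle-equivalence and cohort-replication studies inside their
  runtime budgets.
* Monte-Carlo problem sizes in the test suite: 1000 datasets for oracle
  equivalence; 10 replicate cohorts of 200 observers for parameter
  recovery (the per-cohort MAE fluctuates by ~0.002 around ~0.049, so the
  recovery bounds are asserted on the replicate mean, which estimates the
  population quantity rather than one noisy draw); 200 seeded cohorts of 39
  for effect-recovery calibration; 100-replicate coverage oracles for the
  stimulus generator.
* At n = 39 the absolute Spearman correlation of an uncoupled cohort has
  E|ρ| ≈ 0.13 from sampling noise alone, so the zero-coupling check is a
  bias check on the mean of ρ across replicates, not on mean |ρ|.
* Degenerate inputs are signalled, not silently patched: all-missed gaze
  conditions yield NaN summaries flagged unusable; zero-variance bias
  vectors raise unless exactly null; empty stimulus classes raise with the
  missing class named.

## Known limitations

* The per-participant prior estimate from 100 trials carries sampling noise
  of roughly ±0.05–0.06, which attenuates cohort-level correlations between
  fitted priors and symptom scores relative to the generative coupling.
* The stretched-beta and JZS Bayes factors are principled defaults, but
  they are not the (undocumented) priors behind the originally printed
  Bayes factors, so those printed values are not reproduction targets.
* The procedural face template is a geometric stand-in; no claim is made
  that its detectability in noise matches photographic faces.
* Spearman p-values use the t approximation by default; exact enumeration
  is available only up to n = 8 (full-permutation cost grows factorially).
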
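# facepriors

Bayesian visual priors, breaking-CFS gaze bias, and rank-based Bayes-factor
inference for psychosis-proneness research.

Predictive-coding accounts of psychosis propose that hallucinations and
delusions arise from overly strong prior expectations of meaningful
signals.  `facepriors` is a reusable Python implementation of the
behavioural pipeline used to test that idea in the visual domain on a
general-population cohort:

1. **Face task** — participants judge whether degraded noise images contain
   a face.  A generative Bayesian observer model is fitted per participant:
   the probability of a "face" response is the posterior
   `P = πL / (πL + (1−π)(1−L))`, where the prior π is the headline
   individual-difference measure and the sensory likelihood is
   `L = s·face + (1−s)(1−face)` with sensitivity s.  Both parameters are
   estimated by bounded maximum likelihood (Powell search over [0,1]²),
   with an algebraic closed-form solution available as an oracle because
   the model is saturated in the hit and false-alarm rates.
2. **Gaze task** — faces with direct or averted gaze are suppressed by
   continuous flash suppression; the per-participant *direct gaze bias* is
   mean breakthrough time (averted) − mean breakthrough time (direct),
   computed from correctly localised trials, with a >65%-missed exclusion
   rule and a one-sample t test plus JZS Bayes factor at the group level.
3. **Inference** — Spearman rank correlations between questionnaire totals
   (PDI-21 delusion proneness, CAPS hallucination proneness) and the
   behavioural measures, with default Bayes factors (stretched-beta prior
   for correlations, Cauchy prior for t tests) computed from first
   principles and labelled with Jeffreys evidence bands
   (BF01 > 1 favours "no effect").

The package also ships the face-in-noise **stimulus generator** (circle
noise → multiplicative speckle → face embedding → Gaussian blur → contrast
compression) and a **synthetic cohort generator** that emulates the study
conditions — right-skewed questionnaire totals, detection responses drawn
from the observer model itself, censored lognormal breakthrough times —
with programmable rank coupling between symptom scores and the generative
parameters, so the whole pipeline is testable without any participant data.
See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
import facepriors as fp

# a full synthetic study: 39 participants, 100 face trials, 48 gaze trials
result = fp.run_all(config=fp.CohortConfig(seed=1))

fits = result["fits"]
print(fits["prior"].mean(), fits["sensitivity"].mean())
# 0.4479364110762658 0.748855890464133

for r in result["correlations"]:
    print(f"{r.x} ~ {r.y}: rho={r.rho:.3f} p={r.p_two_sided:.4f} "
          f"BF01={r.bf01:.3f} ({r.evidence_label}) n={r.n}")
# caps_total ~ face_prior: rho=0.456 p=0.0035 BF01=0.082 (strong-for-H1) n=39
# pdi_total ~ face_prior: rho=0.228 p=0.1628 BF01=1.960 (anecdotal) n=39
# caps_total ~ face_sensitivity: rho=-0.193 p=0.2383 BF01=2.564 (anecdotal) n=39
# pdi_total ~ face_sensitivity: rho=-0.026 p=0.8746 BF01=4.955 (substantial-for-null) n=39
# caps_total ~ direct_gaze_bias: rho=0.116 p=0.4935 BF01=3.899 (substantial-for-null) n=37
# pdi_total ~ direct_gaze_bias: rho=0.123 p=0.4690 BF01=3.796 (substantial-for-null) n=37

g = result["group_gaze_test"]
print(f"t({g.df})={g.t:.2f}, BF01={g.bf01:.2g}, mean bias={g.mean_bias:.3f} s")
# t(36)=8.77, BF01=1.8e-08, mean bias=0.804 s
```

Reading the output: the fitted face priors average ≈ 0.45 with a strong
positive rank correlation to CAPS (hallucination proneness) — the coupling
this synthetic cohort was generated with — while sensitivity is uncoupled
by construction; two designed high-miss participants are excluded from the
gaze analysis (n = 37), and the cohort shows a clear positive direct-gaze
bias (direct gaze breaks into awareness ~0.8 s faster).

The same pipeline runs on real CSV tables (trial-level face and gaze data
plus questionnaire totals) via `fp.run_all(mode="data", ...)` or the CLI:

```bash
facepriors simulate-cohort --out cohort/ --seed 7
facepriors fit-face --trials cohort/face_trials.csv --out fits.csv
facepriors analyze-gaze --trials cohort/gaze_trials.csv --out gaze.csv
facepriors run-all --out results/ --seed 7
```

Short narrative scripts, one per capability, live in `examples/`.

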
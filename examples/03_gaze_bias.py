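"""Direct-gaze bias from simulated breaking-CFS trials.

Simulates a small cohort with a programmed 0.67 s direct-gaze advantage
plus one designed high-miss participant, then runs the preprocessing
(correct-localisation filter, >65%-missed exclusion) and the group test.
"""

import numpy as np

from facepriors import CohortConfig, generate_cohort, group_gaze_test
from facepriors.cfs import gaze_summary, gaze_trials_from_frame, summarize_cohort

cfg = CohortConfig(n_participants=20, n_high_miss_participants=1, seed=3)
data = generate_cohort(cfg)

trials = gaze_trials_from_frame(data.gaze_trials)
table = summarize_cohort(trials)
print(table[["participant_id", "mean_rt_direct", "mean_rt_averted",
             "direct_gaze_bias", "miss_fraction", "excluded"]]
      .round(3).to_string(index=False))

summaries = [gaze_summary(pid, t) for pid, t in trials.items()]
res = group_gaze_test(summaries)
print(f"\ngroup test on {res.n} usable participants: "
      f"t({res.df})={res.t:.3f}, p={res.p_two_sided:.2g}, BF01={res.bf01:.3g}")
print("A positive mean bias means direct gaze breaks through suppression faster;")
print("the excluded row is the designed high-miss participant (mask suppressed")
print("nearly every trial, so no reliable breakthrough times exist).")
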
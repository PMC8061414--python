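"""End-to-end run on a synthetic default cohort.

Generates the full study dataset (39 participants: questionnaires, 100 face
trials, 48 gaze trials each), fits every detection model, summarises the
gaze task and prints the six headline rank correlations with Bayes factors.
"""

from facepriors import CohortConfig, run_all

result = run_all(config=CohortConfig(seed=1), out_dir="pipeline_demo")

fits = result["fits"]
print(f"fitted face prior: mean={fits['prior'].mean():.3f} "
      f"(SD {fits['prior'].std(ddof=1):.3f}); "
      f"sensitivity: mean={fits['sensitivity'].mean():.3f}")

print("\npairing                                     n   rho      p    BF01  evidence")
for r in result["correlations"]:
    print(f"{r.x:>10s} ~ {r.y:<20s} {r.n:3d}  {r.rho:+.3f}  {r.p_two_sided:.3f} "
          f"{r.bf01:7.3f}  {r.evidence_label}")

g = result["group_gaze_test"]
print(f"\ngroup direct-gaze test: t({g.df})={g.t:.2f}, BF01={g.bf01:.2g}, "
      f"mean bias={g.mean_bias:.3f} s, n={g.n}")
print("\nThe CAPS ~ face_prior row carries the cohort's programmed coupling (0.50);")
print("sensitivity rows are uncoupled by construction, so their BF01 > 1.")
print("Full report written to pipeline_demo/report.json")
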
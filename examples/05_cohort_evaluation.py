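"""Evaluate threshold-recovery accuracy on a small simulated cohort.

Runs the full closed-loop procedure for a handful of subjects and prints
the per-frequency and pooled error/test-time summary — a scaled-down
version of what scripts/acceptance.py computes on the default 30-subject
cohort.
"""

from abrgp import SessionConfig, default_cohort, evaluate_cohort

profiles = default_cohort(seed=5, n_subjects=6)
result = evaluate_cohort(profiles, SessionConfig(), seed=5)

print(result.summary.to_string(index=False))
print()
print(f"pooled median signed error: {result.pooled_median_error:+.1f} dB HL")
print(f"grand mean absolute error:  {result.grand_mean_abs_error:.1f} dB "
      f"(|error| averaged within subject, then across subjects)")
print("A median near 0 dB means the procedure is unbiased relative to the")
print("simulated ground-truth thresholds; minutes reflect artifact-free epochs.")
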
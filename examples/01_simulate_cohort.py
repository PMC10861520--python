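"""Simulate an RA study cohort and inspect its PRO group structure.

Generates 30 healthy controls, 13 moderate-RA and 15 severe-RA participants
with the default group effect sizes, then prints per-group means of the
patient-reported outcomes.  Healthy controls carry a baseline RAPID-3 of
exactly zero by assignment; RA severity is reflected in higher HAQ-DI/RASIQ
and lower FACIT (fatigue) scores.
"""

from wearra.config import default_config
from wearra.synthetic import cohort_frame, generate_cohort

cfg = default_config(seed=1)
records = generate_cohort(30, 13, 15, cfg)
cohort = cohort_frame(records)

summary = cohort.groupby("group")[
    ["rapid3_baseline", "HAQ-DI", "RASIQ-pain", "FACIT", "age", "bmi"]
].mean().round(2)
print(summary)
print("\nEach row is a group mean over the simulated cohort; RAPID-3 and "
      "HAQ-DI rise with severity while FACIT falls, matching the configured "
      "group distributions.")
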
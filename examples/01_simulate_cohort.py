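"""Simulate a double-probe retrocue cohort and write it as a trial CSV.

The default generative truth encodes the canonical retrocue findings:
higher recall probability for cued items, lower for uncued, and a small
repulsive bias on the first response when the cued item is still pending.
"""

from collections import Counter

from retroprobe import DesignSpec, GenerativeParams, simulate_cohort, write_trials

design = DesignSpec.e1()  # 8 blocks x 60 trials, cue never conveys order
params = GenerativeParams()
cohort = simulate_cohort(design, params, n_subjects=24, seed=7)

write_trials(cohort, "e1_cohort.csv")

counts = Counter(r.condition for r in cohort[0].records)
print(f"subjects: {len(cohort)}")
print(f"trials per subject: {len(cohort[0])}")
print(f"conditions: {dict(counts)}")
# Each subject contributes 480 trials, evenly split over neutral,
# cued-probed-first and cued-probed-second retrocue conditions.
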
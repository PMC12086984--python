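"""Simulate a panel-observed MCI cohort and describe its transitions.

Generates 500 subjects who enter in MCI and are reassessed at irregular
visits until AD diagnosis or 15 years, then tabulates consecutive-visit
transitions and follow-up. The percentages are within-origin shares: of all
visit pairs that start in MCI, how many end in rNC / AD / stay in MCI.
"""

from funmstate import count_transitions, summarize_followup
from funmstate.simulate import SimConfig, generate_cohort

subjects, truth = generate_cohort(SimConfig(n_subjects=500), seed=1)

fu = summarize_followup(subjects)
print(f"{fu['n_subjects']} subjects, {fu['n_observations']} observations")
print(f"follow-up: median {fu['median']:.2f} y, IQR "
      f"({fu['iqr'][0]:.2f}, {fu['iqr'][1]:.2f}), max {fu['max']:.2f} y\n")

print(count_transitions(subjects).to_frame().to_string(index=False))
print("\nEach row counts consecutive visit pairs; percentages are shares "
      "within the origin state.")
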
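"""Collapse prompts to days, apply the 7-consecutive-day rule, compute ICCs.

A day counts toward eligibility only when every symptom and every exposure
has at least one answered prompt; incomplete days break runs, and only
maximal runs of >= 7 consecutive days are analysed.
"""

import emalag as em

cohort = em.simulate_cohort(em.SimConfig(n_participants=40, seed=2))
days = em.aggregate_to_days(cohort)
print(f"{len(days.days)} participant-days after collapsing prompts")

filtered = em.filter_consecutive_runs(days, min_days=7)
print(filtered.exclusion_report.splitlines()[0])

icc = em.icc(filtered)
print("\nwithin-participant, between-day ICC per symptom:")
for s, v in icc.items():
    print(f"  {s:22s} {v:.2f}")
print("\nValues around 0.6-0.75 mean stable participant differences "
      "dominate day-to-day fluctuation — the motivation for participant "
      "random intercepts in the model.")
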
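"""Quality-control a diary table and select one diary per participant.

Corruption is injected at known rates so each removal stage of the QC
report can be compared with what was planted: >90 min of missing time,
fewer than 7 activity episodes, missing basic activities, ineligible
placeholder codes (9960-9999), and diaries reporting no sleep.
"""

from timeuse_coda import (
    CorruptionRates,
    GeneratorConfig,
    apply_qc,
    corrupt_diaries,
    generate_population,
    select_one_diary_per_participant,
)

participants, diaries, _ = generate_population(GeneratorConfig(n_participants=800, seed=11))
rates = CorruptionRates(
    missing_time=0.02, few_episodes=0.02, missing_basic=0.02, ineligible=0.10, no_sleep=0.005
)
diaries, planted = corrupt_diaries(diaries, rates, seed=12)
print("planted corruptions by rule:")
print(planted["rule"].value_counts().to_string())

retained, report = apply_qc(diaries, participants, min_age=16)
print()
for line in report.log_lines():
    print(line)

selected = select_one_diary_per_participant(retained, seed=13)
print(f"\nafter selection: {selected['diary_id'].nunique()} diaries, one per participant")
# The per-stage removal counts match the planted counts: general QC catches
# the first three rules, the eligible-24h stage catches placeholder codes,
# and the no-sleep stage the diaries whose sleep was removed.
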
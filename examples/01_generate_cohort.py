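"""Generate a seeded synthetic EMA cohort and inspect its design.

The generator emulates a one-week post-quit observation window: 52 lapsers
and 40 abstainers, five prompted EMAs per day (one wake-anchored diary plus
four random prompts over 16 waking hours), self-initiated assessments, and
risk-factor prevalences conditional on each EMA's eventual proximity to the
first lapse."""

from lapserisk import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(master_seed=7))

n_participants = len(cohort.roster)
n_lapsers = int(cohort.roster["first_lapse_time"].notna().sum())
print(f"participants: {n_participants} ({n_lapsers} lapsers, "
      f"{n_participants - n_lapsers} abstainers)")
print(f"completed EMAs: {len(cohort.ema)} "
      f"(mean {len(cohort.ema) / n_participants:.1f} per participant)")
print("records by eventual proximity class:", cohort.meta)
print(cohort.ema.head(3).to_string(index=False))
# The class counts show how many EMAs will survive pre-lapse filtering:
# post-lapse records are collected but never enter the risk analyses.
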
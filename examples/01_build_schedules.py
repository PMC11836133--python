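"""Build the two perturbation schedules and show their geometry.

An abrupt block holds a constant seen/felt mismatch between two unperturbed
baselines; a sinusoidal block sweeps the mismatch through three sine cycles,
quantised to the 0.5 mm grid of the physical felt objects.
"""

from graspadapt import schedules as sched

abrupt = sched.make_abrupt_schedule(
    sched.ScheduleSpec(schedule_kind="abrupt", magnitude=12.0), [40.0] * 24
)
print("abrupt (+12 mm on a 40 mm object):")
print("  felt sizes:", abrupt.felt.tolist())

sinus = sched.make_sinusoidal_schedule(
    sched.ScheduleSpec(schedule_kind="sinusoidal", magnitude=12.0,
                       n_trials=36, n_cycles=3), [44.0] * 36
)
print("\nsinusoidal (peak 12 mm, period 12):")
print("  first cycle of mismatches:", sinus.mismatch[:12].tolist())

specs = sched.enumerate_block_set("main")
print(f"\nmain experiment: {len(specs)} blocks, abrupt magnitudes "
      f"{sorted(s.magnitude for s in specs if s.schedule_kind == 'abrupt')}")
# Felt sizes snap to 0.5 mm (e.g. 12*sin(pi/3) = 10.39 -> 10.5) and trial 1 of
# every sinusoidal block is exactly unperturbed.
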
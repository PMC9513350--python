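"""Time-division semi-parallel output: 64 channels in 8 timeslots.

Reproduces the bench configuration in which every generator fires one of
its eight channels per slot (~±30 μA biphasic pulses) inside a ~4936 μs
window, and prints the repetition-rate ceiling for 0.4 ms pulses.
"""

from icmsim import ChipRegisterFile, PulseSpec, build_schedule, max_repetition_rate

regfile = ChipRegisterFile(
    stp=(1,) * 64,                                # all 64 channels enabled
    sts=tuple(i % 8 for i in range(64)),          # channel k fires in slot k
)
spec = PulseSpec(30, 30, 200, 200)                # 400 us biphasic pulse
sched = build_schedule(regfile, {i: spec for i in range(64)}, slot_duration_us=617.0)

print(f"{len(sched.events)} pulses scheduled")
print(f"slot {sched.slot_duration_us:.0f} us x 8 = window {sched.window_duration_us:.0f} us")
slot0 = [e for e in sched.events if e.slot == 0]
print(f"slot 0 carries generators {[e.address.generator for e in slot0]} simultaneously")

rate = max_repetition_rate(400.0)
print(f"max per-channel repetition rate at 0.4 ms pulses: {rate:.1f} Hz (~{int(rate)} Hz)")
# One pulse per channel per window: 8 slots x (400 + 7.8) us limits each
# channel to ~306 Hz even though 8 channels run in parallel at any instant.
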
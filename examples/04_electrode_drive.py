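"""Driving electrode-interface loads: compliance clamping and shorting.

Drives the two bench interface models (33.7 kΩ and 325 kΩ at 1 kHz) with an
~±80 μA biphasic pulse. Into the high-impedance load the terminal voltage
hits the ±2.42 V compliance limit and the delivered current sags below
command — the signature a dry-bench oscillogram shows.
"""

import numpy as np

from icmsim import GeneratorSettings, PulseSpec, bench_load, impedance_magnitude, simulate_drive
from icmsim.current_generator import synthesize_pulse
from icmsim.electrode_load import short_to_reference

wf = synthesize_pulse(PulseSpec(80, 80, 200, 200), GeneratorSettings())

for name in ("metal_33k7", "small_tip_325k"):
    load = bench_load(name)
    res = simulate_drive(load, wf)
    delivered = np.sum(np.abs(res.actual_uA)) * wf.dt_us  # total |charge|, pC
    commanded = np.sum(np.abs(res.commanded_uA)) * wf.dt_us
    print(f"{name}: |Z|(1 kHz) = {impedance_magnitude(load, 1e3) / 1e3:.1f} kOhm")
    print(f"  peak |V_out| {np.abs(res.terminal_voltage_V).max():.2f} V "
          f"(limit {load.v_limit_v} V), clamped intervals: {len(res.clamped_intervals_us)}")
    print(f"  delivered {delivered:.0f} / commanded {commanded:.0f} pC "
          f"({delivered / commanded:.0%})")

# residual interface charge decays with tau = Rs*Cp when shorted to Vref
load = bench_load("metal_33k7")
tau = load.r_series_ohm * load.c_parallel_f
print(f"shorting 1 V residual for 5 tau ({5 * tau * 1e6:.0f} us) leaves "
      f"{short_to_reference(load, 1.0, 5 * tau) * 1e3:.1f} mV")
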
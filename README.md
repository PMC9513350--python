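# icmsim

A register-accurate software emulator of a 64-channel, time-division
multiplexed intracortical microstimulation (ICMS) module — the kind of
multichannel ASIC used to evoke phosphenes in cortical visual prostheses —
together with an electrode–electrolyte interface circuit model and a
synthetic cortical dose-response layer for closed-loop desk testing.

It is written for neural-engineering groups who need to develop and test
stimulation control software (register streams, pattern pipelines, charge
budgets, scheduling) without the fabricated chip, the bench rig, or an
animal on the table.

## What is modelled

**The chip.** One module chip holds eight 8-channel current generators
(64 electrodes). Stimulus parameters live in three on-chip register groups
of decreasing update rate — Reg1 (64 bits, stimulation on/off positions),
Reg2 (192 bits, timeslot sequence) and Reg3 (1160 bits, amplitudes,
reference flags, pulse-width trims, circuit settings). Up to 2⁶ = 64 chips
(4096 electrodes) share a 10 Mbps serial bus; each frame carries a 6-bit
chip-ID header and only the matching chip applies it. Frame lengths follow
from the bus arithmetic: 73 bits per Reg1 update (7.3 μs/chip) and 1362
bits per initialization frame (136.2 μs/chip).

**The pulses.** Amplitude is set by a 6-bit DAC against a selectable
±100…±400 μA full scale, so the resolution at the default range is
100/2⁶ ≈ 1.56 μA. A biphasic pulse with a one-LSB mismatch between its
phases leaves a net charge of up to *resolution × phase duration*
(±156 pC at 0.1 ms/phase); a 4-bit code trims the second phase's width in
~1.95 μs steps to cancel it. Output is time-division semi-parallel: eight
timeslots per window, one channel per generator per slot, which caps the
per-channel repetition rate at 10⁶/(8·(t_pulse + 7.8 μs)) ≈ 306 Hz for
0.4 ms pulses.

**The load.** The electrode–electrolyte interface is the standard series
resistance + parallel RC equivalent circuit. The emulated current source is
ideal inside the ±2.42 V compliance window and clamps beyond it, so driving
a high-impedance load near ±80 μA reproduces the characteristic sag of the
delivered current. Integration is exact per-step exponential (the system is
piecewise linear), with analytic resolution of the clamp crossing.

**The tissue (synthetic).** Normalized cortical response amplitude versus
charge per phase *q* follows a threshold-shifted Hill function

    R(q) = (q − I_th)^N / ((q − I_th)^N + (I_50 − I_th)^N)   for q > I_th,  else 0

with defaults I_th = 0.9 nC/phase, I_50 = 2.4 nC/phase, N = 2.5. A movie
generator emulates voltage-sensitive-dye imaging (ΔF/F, 100×100 pixels over
6.25×6.25 mm at 1000 fps): focal responses peaking ~13 ms post-stimulus,
spatial spread over the first milliseconds, a hyperpolarizing undershoot
near 100 ms, and inhibitory attenuation of pulses arriving within ~20 ms of
a predecessor.

## Worked example

```python
from icmsim import (GeneratorSettings, PulseSpec, amplitude_resolution,
                    charge_imbalance, optimize_pw_adjust, synthesize_pulse)

s = GeneratorSettings(max_range_code=0)          # ±100 μA range
res = amplitude_resolution(s)                    # 1.5625 μA

bad = PulseSpec(19 * res, 20 * res, 200, 200)    # anodic phase 1 LSB high
print(charge_imbalance(synthesize_pulse(bad, s)))
print(optimize_pw_adjust(bad, s))
```

prints

```
312.5
(-5, 6.25)
```

— the one-LSB amplitude mismatch leaves 312.5 pC of net charge per pulse;
trimming the anodic phase by 5 steps (−9.75 μs) reduces the residual to
6.25 pC, the same trim-and-measure procedure used on the bench. The
`examples/` directory walks through each capability the same way
(registers and bus timing, TDM scheduling, compliance clamping into the
two bench interface models, the spike-image→Reg1 pattern pipeline, and
dose-response fitting with synthetic ΔF/F movies); each script prints the
numbers it computes and what they mean.

A thin CLI mirrors the common tasks:

```sh
icmsim bus-timing --chips 64
icmsim schedule reg.json pulses.json --out schedule.csv
icmsim fit-hill --in points.csv
icmsim synth-vsd --config scene.json --seed 1 --out movie.h5
icmsim pattern-run --input f0.pgm --input f1.pgm --threshold 0.5 --out out/
```

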
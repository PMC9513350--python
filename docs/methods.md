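# Methods

This note records the models, parameter choices and numerical decisions
behind `icmsim`, and what the synthetic layers do and do not claim about
real hardware and real cortex.

## Register model and bus protocol

The register map is reproduced bit-for-bit: per-channel STP (1 bit), STS
(3 bits), AP/CP (6 bits each), RP (1 bit), PA (4 bits), and per-bank MA,
ICS (2 bits) and OTR (32 bits). Group sizes (64/192/1160 bits) are always
computed by summing these field widths, never stored as constants, so the
layout is the single source of truth. The OTR ("others") payload is carried
opaquely; nothing is known about its internal structure.

Serialization needed three decisions the hardware documentation leaves
open, all fixed and documented in `registers.py`: fields serialize in
register-map row order, entries in generator-major flat channel order, each
value MSB-first; the signed PA code (−7..+8) is stored offset-binary
(value+7); and the framing overhead is 3 bits on Reg1 frames and 4 bits on
init frames, all zero. The framing *counts* are not free: the per-chip
update times at 10 Mbps (7.3 μs and 136.2 μs) fix total frame lengths of 73
and 1362 bits, and the header+payload accounts for 70 and 1358 of them. Any
fixed convention round-trips; these are verified by encode/decode bijection
tests over random register contents and by a 64-chip broadcast test showing
a frame mutates exactly the chip whose ID matches its header.

The PA trim is stored per channel (256 bits in the register map) although
the trim circuit is described as acting per generator; the emulator follows
the register map and applies the active channel's code.

## Current generation

Amplitude quantization rounds the commanded current to the nearest of 64
codes (ties toward zero — the hardware behavior is unspecified, and this
choice never overstates the delivered charge), saturating at code 63, so a
full-scale command quantizes to 63/64 of full scale. Optional per-polarity
gain factors (`anodic_gain`, `cathodic_gain`, default 1.0) model the
current-mirror mismatch fabricated parts show between the phases; they are
off by default so the ideal generator is exactly charge-balanced.

Waveforms are piecewise-constant on a uniform grid, default dt = 0.1 μs
(≥19 samples per 1.95 μs trim step); phase durations round to the nearest
sample. Where a computation needs the 1.95 μs step represented exactly
(imbalance sweeps, trim optimality), dt = 0.05 μs is used, since
1.95/0.05 = 39 exactly. Rise/fall are instantaneous; the fabricated part's
≤5 μs rise time is not modelled, which only affects sub-μs charge details.

Charge accounting integrates the sampled trace by rectangles (exact for
piecewise-constant signals aligned to the grid): `phase_charge` returns the
cathodic and anodic magnitudes in pC, `charge_imbalance` their signed
difference. The width-trim optimizer exhaustively evaluates all 16 PA codes
on synthesized waveforms and returns the code minimizing |net charge|,
ties toward code 0; by construction its residual never exceeds the
unadjusted imbalance.

## TDM scheduling

Slots are uniform; the default slot length is the longest enabled pulse
plus the multiplex switching time (minimum 7.8 μs, configurable upward). A
fixed slot length can be imposed to reproduce a given recording window
(e.g. 617 μs slots → 4936 μs window). Two enabled channels of one generator
sharing an STS code is a hard scheduling error, not a silent drop.
Reference-flagged channels (RP=1) are treated as connected returns that
emit no stimulus event.

## Electrode interface

The interface is Rs + (Rp ∥ Cp) with a hard ±2.42 V compliance clamp. Both
operating modes are linear first-order systems, so the simulator advances
the capacitor voltage with exact exponential updates (time constants Rp·Cp
in source mode, (Rs∥Rp)·Cp under clamp) and solves the source→clamp
crossing time analytically within a step; there is no integrator drift, and
the recorded terminal voltage never exceeds the limit beyond 1 mV. The
clamp is hard (ideal current source up to the limit, ideal voltage source
at it); any soft compression the silicon shows near the rail is not
modelled. Shorting to reference discharges Cp through Rs (the dominant
series element) with τ = Rs·Cp.

The two named bench loads reproduce the only published facts about the
physical test circuits — |Z|(1 kHz) = 33.7 kΩ and 325 kΩ with Rs ≈ 1 kΩ.
That is one equation in two unknowns, so Cp was fixed per model at a
realistic double-layer value for the electrode scale involved (2 nF for the
metal-electrode model, 0.2 nF for the small-tip model) and Rp solved by
bracketing root-find; the fitted values are frozen in
`src/icmsim/data/bench_loads.json` and a test recomputes |Z|(1 kHz) from
them. Inrush suppression is idealized: a potential mismatch V at switch
connection produces a V/Rs peak when suppression is off and zero when the
pre-equalization is on.

## Pattern pipeline

The retinal circuit emulator that fed the original demonstration is
replaced by a minimal transient-ON stand-in: block-average the input to
64×64, spike where intensity rose by more than a threshold since the
previous frame. This captures exactly what the downstream pipeline needs
(sparse binary frames at 5 ms steps) and nothing of retinal dynamics.

Block/chip and pixel/channel mappings are fixed conventions (row-major
blocks, chip = 8·(row/8)+(col/8); block pixel (r,c) → generator r+1,
channel c+1), since the demonstration's physical wiring is not public. Any
fixed bijection reproduces the demonstration; with this one the end-to-end
identity — spike frame → blocks → Reg1 bus frames → 64-chip register array
→ LED render → reassembled frame — holds exactly and is tested on 100
random frames. Per-frame bus occupancy is 64×73 bits = 467.2 μs at 10 Mbps,
consistent with the bus-timing module and comfortably inside the 5 ms frame
step.

## Synthetic cortical response

The "modified Hill" dose-response is implemented as the threshold-shifted
Hill form (see README); the published fit reported only the three parameter
values (~0.9 / ~2.4 nC/phase, N ≈ 2.5) without the closed form, so adopting
the standard sigmoid with exactly those three parameters and their stated
meanings is an interpretation, stated prominently here. The defaults are
used as generator parameters, never as fitting targets: the underlying
per-electrode data are not published, so no test asserts recovery of those
specific numbers from data.

Fitting is bounded nonlinear least squares over (I_th, I_50−I_th, N) from a
fixed 12-point multi-start grid spanning the data range; it is
deterministic, recovers noiseless synthetic parameters to ~10⁻⁶ relative,
and raises on degenerate (spread-free) data. A seeded Monte-Carlo test (200
replicates, σ = 0.05 on an 8-level charge series built from the DAC's
quantized amplitudes at 0.2 ms/phase) checks median |ΔI_50|/I_50 < 10% and
bias < 5% — this is the package's desk-scale stand-in for the in-vivo fit.

The ΔF/F movie generator sums, per stimulus, a separable contribution:
Hill amplitude × spreading spatial Gaussian × unit-peak temporal kernel.
Parameters, with defaults and grounds:

| parameter | default | meaning |
|---|---|---|
| `t_peak_ms` | 13 | kernel peak time (observed 11–15 ms range, midpoint) |
| `undershoot_time_ms` / `undershoot_depth` / `undershoot_sigma_ms` | 100 / 0.15 / 30 | Gaussian hyperpolarizing undershoot near 100 ms |
| `rise_sharpness` | 2 | gamma-kernel exponent; sets rise/decay width |
| `spatial_sigma_mm` | 0.15 | initial excitation footprint σ |
| `sigma_growth` / `growth_tau_ms` | 2 / 5 | footprint grows toward 2σ over ~5 ms (propagation) |
| `inhibition_window_ms` / `inhibition_gain` | 20 / 0.5 | pulses within 20 ms of a predecessor are halved; gains compound along a train |
| `bipolar_gain` | 1.2 | amplitude factor for sources flagged as bipolar-pair members |

The temporal kernel (t/t_p)^a·exp(a(1−t/t_p)) peaks at exactly t_p with
unit height, so noiseless peak times are grid-exact. `spatial_sigma_mm` and
its growth were chosen so that paired sources ≥0.6 mm apart produce two
discernible excitation loci in the 3–4 ms frames while ~0.3 mm pairs merge
(two equal Gaussians resolve iff separation > 2σ; σ(3.5 ms) ≈ 0.23 mm) —
the qualitative bipolar observation made exact under the defaults.
Sequential inhibition is a deliberate caricature: a single multiplicative
gain chained along pulses, not a conductance model. The bipolar gain is a
free choice (no quantitative value is published), representing the
larger-amplitude responses bipolar configurations showed. Noise is i.i.d.
Gaussian per pixel per frame with σ/√n_trials under trial averaging; movies
are bit-reproducible given a seed.

What passing tests show — and don't. The emulator's register, timing and
charge arithmetic are exact models of the documented design, so those tests
verify the implementation against the design's own arithmetic. The response
layer, by contrast, emulates phenomenology (peak timing, spread, dose
sigmoid, inhibition, two-locus geometry); its tests show the generator and
analysis code are mutually consistent and numerically exact, not that
cortex behaves this way. Real VSD data add correlated optical noise,
heartbeat/breathing artifacts, anisotropic spread along cortical maps, and
electrode-to-electrode variability, none of which are generated here.

## Problem sizes

Default test problem sizes: 100-frame pipeline identity sweeps, 200-replicate
Monte-Carlo fits, 64×64 = 4096-pair (190 after the ≤1-LSB filter) imbalance
sweeps, and drive simulations of 2–6×10³ samples; the full suite runs in
well under a minute on one CPU, and `scripts/acceptance.py` in seconds.
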
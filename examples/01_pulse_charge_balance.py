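"""Biphasic pulse synthesis and charge-imbalance trimming.

Commands a nominally symmetric ±30 μA, 200 μs/phase pulse, then forces a
one-LSB anodic excess (the kind of current-mirror mismatch a fabricated
chip shows) and lets the 4-bit pulse-width adjustment cancel the net charge.
"""

from icmsim import (
    GeneratorSettings,
    PulseSpec,
    amplitude_resolution,
    charge_imbalance,
    optimize_pw_adjust,
    phase_charge,
    synthesize_pulse,
)

settings = GeneratorSettings(max_range_code=0)  # ±100 μA range
res = amplitude_resolution(settings)
print(f"amplitude resolution: {res:.4f} uA (100 uA / 64 codes)")

spec = PulseSpec(30, 30, 200, 200)
wf = synthesize_pulse(spec, settings)
cath, anod = phase_charge(wf)
print(f"symmetric pulse: cathodic {cath:.1f} pC, anodic {anod:.1f} pC, "
      f"net {charge_imbalance(wf):.1f} pC")

# one LSB of anodic excess -> 1.5625 uA x 200 us = 312.5 pC of net charge
imbalanced = PulseSpec(19 * res, 20 * res, 200, 200)
print(f"1-LSB anodic excess: net {charge_imbalance(synthesize_pulse(imbalanced, settings)):.1f} pC")

code, residual = optimize_pw_adjust(imbalanced, settings)
print(f"best width-adjust code {code:+d} ({code * 1.95:+.2f} us on the second phase) "
      f"-> residual {residual:.2f} pC")
# The optimizer shortens the anodic phase just enough that the excess charge
# drops from hundreds of pC to a few pC, mirroring the bench trimming procedure.
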
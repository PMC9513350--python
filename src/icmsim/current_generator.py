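"""One 8-channel biphasic current generator: DAC quantization, pulse
synthesis, pulse-width adjustment and charge accounting.

The generator sets stimulus amplitude with a 6-bit code against a selectable
full scale of ~±100 to ±400 μA (2-bit max-amplitude code, ~100 μA steps), so
the amplitude resolution at the default ±100 μA range is 100/64 ≈ 1.56 μA.
Because the cathodic and anodic phases are produced by separate current
mirrors, a one-LSB mismatch between the two phase amplitudes leaves a net
charge per pulse of up to resolution × phase duration (±156 pC for
0.1 ms/phase at the ±100 μA range). A 4-bit code (−7..+8) trims the second
phase's duration in ~1.95 μs steps to cancel that imbalance.

Conventions: cathodic current is negative, anodic positive. Charge is in
picocoulombs (μA × μs). Waveforms are piecewise-constant and realized on a
uniform sample grid; phase durations are rounded to the nearest sample.
Rise/fall times are treated as instantaneous (the fabricated part reports
≤5 μs 10–90% rise, not modelled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

AMPLITUDE_BITS = 6
N_AMPLITUDE_CODES = 2 ** AMPLITUDE_BITS  # 64
PW_STEP_US = 1.95  # second-phase width adjustment step
PW_ADJUST_MIN, PW_ADJUST_MAX = -7, 8  # 4-bit signed code
DEFAULT_DT_US = 0.1


@dataclass(frozen=True)
class GeneratorSettings:
    """Per-generator circuit settings.

    ``max_range_code`` is the 2-bit MA register code; full scale is
    ~100 μA × (code + 1). The optional anodic/cathodic gain factors model
    the current-mirror mismatch seen in fabricated parts (resolution differs
    slightly between the two polarities); both default to the ideal 1.0.
    """

    max_range_code: int = 0
    anodic_gain: float = 1.0
    cathodic_gain: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.max_range_code <= 3:
            raise ValueError(f"max_range_code must be 0..3, got {self.max_range_code}")
        if self.anodic_gain <= 0 or self.cathodic_gain <= 0:
            raise ValueError("gain factors must be positive")

    @property
    def full_scale_uA(self) -> float:
        return 100.0 * (self.max_range_code + 1)

    @property
    def resolution_uA(self) -> float:
        return self.full_scale_uA / N_AMPLITUDE_CODES


def amplitude_resolution(settings: GeneratorSettings) -> float:
    """Smallest amplitude step in μA: full scale divided by 2**6."""
    return settings.resolution_uA


def quantize_amplitude(cmd_amp_uA: float, settings: GeneratorSettings) -> tuple[int, float]:
    """Map a commanded amplitude to the nearest 6-bit DAC code.

    Returns ``(code, actual_amp_uA)`` with ``actual = code × resolution``.
    Rounds to nearest, ties toward zero; codes saturate at 63, so commands at
    the full scale quantize to 63 × resolution (98.4375 μA at the ±100 μA
    range). The quantization error never exceeds half a resolution step for
    commands below the top code.
    """
    if cmd_amp_uA < 0 or cmd_amp_uA > settings.full_scale_uA:
        raise ValueError(
            f"command {cmd_amp_uA} μA outside 0..{settings.full_scale_uA} μA range"
        )
    q = cmd_amp_uA / settings.resolution_uA
    code = math.floor(q + 0.5)
    if q - math.floor(q) == 0.5:  # tie: toward zero
        code = math.floor(q)
    code = min(code, N_AMPLITUDE_CODES - 1)
    return code, code * settings.resolution_uA


@dataclass(frozen=True)
class PulseSpec:
    """Commanded biphasic pulse parameters (amplitudes in μA, times in μs)."""

    cathodic_amp_uA: float
    anodic_amp_uA: float
    cathodic_dur_us: float
    anodic_dur_us: float
    interphase_gap_us: float = 0.0
    order: Literal["cathodic_first", "anodic_first"] = "cathodic_first"
    pw_adjust_code: int = 0

    def __post_init__(self) -> None:
        if self.cathodic_amp_uA < 0 or self.anodic_amp_uA < 0:
            raise ValueError("amplitudes are magnitudes and must be >= 0")
        if self.cathodic_dur_us <= 0 or self.anodic_dur_us <= 0:
            raise ValueError("phase durations must be positive")
        if self.interphase_gap_us < 0:
            raise ValueError("interphase gap must be >= 0")
        if self.order not in ("cathodic_first", "anodic_first"):
            raise ValueError(f"unknown phase order {self.order!r}")
        if not PW_ADJUST_MIN <= self.pw_adjust_code <= PW_ADJUST_MAX:
            raise ValueError(
                f"pw_adjust_code must be {PW_ADJUST_MIN}..{PW_ADJUST_MAX}, got {self.pw_adjust_code}"
            )

    @property
    def second_phase_nominal_us(self) -> float:
        return self.anodic_dur_us if self.order == "cathodic_first" else self.cathodic_dur_us

    @property
    def second_phase_adjusted_us(self) -> float:
        """Second-phase duration after the 1.95 μs/step width adjustment."""
        return self.second_phase_nominal_us + self.pw_adjust_code * PW_STEP_US

    @property
    def total_duration_us(self) -> float:
        first = self.cathodic_dur_us if self.order == "cathodic_first" else self.anodic_dur_us
        return first + self.interphase_gap_us + self.second_phase_adjusted_us


@dataclass(frozen=True)
class CurrentWaveform:
    """A sampled current trace on a uniform time grid (μs / μA)."""

    sample_times_us: np.ndarray
    current_uA: np.ndarray
    spec: PulseSpec | None = None
    settings: GeneratorSettings | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_us, dtype=float)
        i = np.asarray(self.current_uA, dtype=float)
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("sample_times_us and current_uA must be equal-length 1-D arrays")
        object.__setattr__(self, "sample_times_us", t)
        object.__setattr__(self, "current_uA", i)

    @property
    def dt_us(self) -> float:
        return float(self.sample_times_us[1] - self.sample_times_us[0])

    def to_csv(self, path: str | Path, voltage_V: np.ndarray | None = None) -> None:
        df = pd.DataFrame({"time_us": self.sample_times_us, "current_uA": self.current_uA})
        if voltage_V is not None:
            df["voltage_V"] = voltage_V
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CurrentWaveform":
        df = pd.read_csv(path)
        return cls(df["time_us"].to_numpy(), df["current_uA"].to_numpy())


def synthesize_pulse(
    spec: PulseSpec,
    settings: GeneratorSettings | None = None,
    dt_us: float = DEFAULT_DT_US,
) -> CurrentWaveform:
    """Generate the current trace the module would emit for a pulse spec.

    Both amplitudes are quantized to the 6-bit DAC and scaled by the
    per-polarity gain factors; the second phase's duration is the nominal
    duration plus ``pw_adjust_code × 1.95 μs``. Samples hold the value of the
    interval [t, t+dt); the trace ends with one zero sample.
    """
    if settings is None:
        settings = GeneratorSettings()
    if dt_us <= 0 or dt_us > 1.0:
        raise ValueError("dt_us must be in (0, 1] μs to resolve the 1.95 μs adjustment step")
    if spec.second_phase_adjusted_us <= 0:
        raise ValueError(
            f"adjusted second-phase duration {spec.second_phase_adjusted_us:.3f} μs is not positive"
        )

    _, cath = quantize_amplitude(spec.cathodic_amp_uA, settings)
    _, anod = quantize_amplitude(spec.anodic_amp_uA, settings)
    cath = -cath * settings.cathodic_gain
    anod = anod * settings.anodic_gain

    if spec.order == "cathodic_first":
        segments = [
            (cath, spec.cathodic_dur_us),
            (0.0, spec.interphase_gap_us),
            (anod, spec.second_phase_adjusted_us),
        ]
    else:
        segments = [
            (anod, spec.anodic_dur_us),
            (0.0, spec.interphase_gap_us),
            (cath, spec.second_phase_adjusted_us),
        ]

    values: list[np.ndarray] = []
    for amp, dur in segments:
        n = int(round(dur / dt_us))
        values.append(np.full(n, amp))
    current = np.concatenate(values + [np.zeros(1)])
    times = np.arange(current.size) * dt_us
    return CurrentWaveform(times, current, spec=spec, settings=settings)


def phase_charge(waveform: CurrentWaveform) -> tuple[float, float]:
    """Charge magnitudes delivered in the cathodic and anodic phases (pC).

    Rectangular integration of the sampled trace, sign-separated:
    ``cathodic`` integrates the negative samples (returned as a magnitude),
    ``anodic`` the positive samples.
    """
    i = waveform.current_uA
    dt = waveform.dt_us
    cathodic = float(-i[i < 0].sum() * dt)
    anodic = float(i[i > 0].sum() * dt)
    return cathodic, anodic


def charge_imbalance(waveform: CurrentWaveform) -> float:
    """Net charge over the whole pulse window (pC): anodic − cathodic.

    Zero for a perfectly balanced pulse; positive when the anodic phase
    delivers excess charge.
    """
    cathodic, anodic = phase_charge(waveform)
    return anodic - cathodic


def optimize_pw_adjust(
    spec: PulseSpec,
    settings: GeneratorSettings | None = None,
    dt_us: float = DEFAULT_DT_US,
) -> tuple[int, float]:
    """Exhaustively pick the 4-bit width-adjustment code that minimizes
    the absolute charge imbalance of a pulse.

    Mirrors the bench procedure: amplitudes and durations are set first,
    then the second-phase width is trimmed while the emitted current is
    measured. All 16 codes are tried; ties break toward code 0 (then toward
    the smaller magnitude code). Returns ``(best_code, residual_imbalance)``.
    """
    if settings is None:
        settings = GeneratorSettings()
    best: tuple[float, int, int] | None = None
    best_resid = 0.0
    for code in range(PW_ADJUST_MIN, PW_ADJUST_MAX + 1):
        trial = PulseSpec(
            cathodic_amp_uA=spec.cathodic_amp_uA,
            anodic_amp_uA=spec.anodic_amp_uA,
            cathodic_dur_us=spec.cathodic_dur_us,
            anodic_dur_us=spec.anodic_dur_us,
            interphase_gap_us=spec.interphase_gap_us,
            order=spec.order,
            pw_adjust_code=code,
        )
        if trial.second_phase_adjusted_us <= 0:
            continue
        imb = charge_imbalance(synthesize_pulse(trial, settings, dt_us))
        key = (abs(imb), abs(code), code)
        if best is None or key < best:
            best = key
            best_resid = imb
    assert best is not None
    return best[2], best_resid
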
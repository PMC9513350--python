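"""Multi-chip bus arithmetic: update times, channel counts, frame-rate
feasibility.

Up to 64 module chips (6-bit ID space) share one serial bus, default
10 Mbps. Register updates run strictly chip-by-chip with no inter-frame
gap, so phase times are exact rational multiples of the frame lengths:
an initialization frame (Reg2+Reg3) is 1362 bits → 136.2 μs/chip and
8.7168 ms for 64 chips; a stimulation-phase Reg1 frame is 73 bits →
7.3 μs/chip and 467.2 μs for 64 chips. 64 chips × 64 channels give 4096
electrodes, and the 467.2 μs position update fits comfortably inside a
20 ms (50 fps) pattern frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .registers import MAX_CHIPS, N_CHANNELS, frame_length_bits

DEFAULT_BITRATE = 10_000_000
DEFAULT_FRAME_PERIOD_MS = 20.0


@dataclass(frozen=True)
class SystemConfig:
    """A multi-chip stimulation system on one shared bus."""

    n_chips: int = MAX_CHIPS
    bitrate: int = DEFAULT_BITRATE
    frame_period_ms: float = DEFAULT_FRAME_PERIOD_MS

    def __post_init__(self) -> None:
        if not 0 <= self.n_chips <= MAX_CHIPS:
            raise ValueError(f"n_chips must be 0..{MAX_CHIPS} (6-bit ID space)")
        if self.bitrate <= 0:
            raise ValueError("bitrate must be positive")
        if self.frame_period_ms <= 0:
            raise ValueError("frame_period_ms must be positive")


def init_phase_time(cfg: SystemConfig) -> float:
    """Seconds to load Reg2+Reg3 into every chip (1362 bits per chip)."""
    return float(Fraction(cfg.n_chips * frame_length_bits("init"), cfg.bitrate))


def reg1_update_time(cfg: SystemConfig) -> float:
    """Seconds to rewrite every chip's stimulation positions (73 bits per chip)."""
    return float(Fraction(cfg.n_chips * frame_length_bits("reg1"), cfg.bitrate))


def total_channels(cfg: SystemConfig) -> int:
    """Stimulating electrodes in the system: 64 per chip."""
    return N_CHANNELS * cfg.n_chips


def frame_rate_feasible(cfg: SystemConfig) -> tuple[bool, float]:
    """Can the bus rewrite all stimulation positions within one pattern frame?

    Returns ``(feasible, overhead_fraction)`` where the overhead fraction is
    the Reg1 update time divided by the frame period (≈2.34% for 64 chips at
    10 Mbps and 20 ms frames).
    """
    update = reg1_update_time(cfg)
    period = cfg.frame_period_ms * 1e-3
    return update < period, update / period
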
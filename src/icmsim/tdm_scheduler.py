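"""Eight-timeslot time-division semi-parallel output scheduling.

Each of a chip's eight current generators drives at most one of its eight
channels per timeslot; the STS register code (0..7) assigns every channel to
a slot. A stimulation window is eight equal slots; a slot must be long
enough for the longest enabled pulse plus the ~7.8 μs multiplex switching
time. With 0.4 ms biphasic pulses this caps the per-channel repetition rate
at 10^6 / (8 × 407.8) ≈ 306 Hz. In the bench demonstration a ~4936 μs
window (617 μs slots) carried one ~±30 μA pulse per generator per slot,
64 pulses per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .current_generator import (
    CurrentWaveform,
    DEFAULT_DT_US,
    GeneratorSettings,
    PulseSpec,
    synthesize_pulse,
)
from .registers import ChannelAddress, ChipRegisterFile, N_CHANNELS

MIN_SWITCH_TIME_US = 7.8
N_SLOTS = 8


class SlotConflictError(ValueError):
    """Two enabled channels of one generator were assigned the same timeslot."""


@dataclass(frozen=True)
class StimEvent:
    address: ChannelAddress
    slot: int
    start_us: float
    waveform: CurrentWaveform

    @property
    def duration_us(self) -> float:
        return float(self.waveform.sample_times_us[-1])


@dataclass(frozen=True)
class StimSchedule:
    """Timeline of channel pulse events within one stimulation window."""

    events: tuple[StimEvent, ...]
    slot_duration_us: float

    @property
    def window_duration_us(self) -> float:
        return N_SLOTS * self.slot_duration_us

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "generator": [e.address.generator for e in self.events],
                "channel": [e.address.channel for e in self.events],
                "slot": [e.slot for e in self.events],
                "start_us": [e.start_us for e in self.events],
                "duration_us": [e.duration_us for e in self.events],
            }
        ).to_csv(path, index=False)


def build_schedule(
    regfile: ChipRegisterFile,
    specs: Mapping[int, PulseSpec],
    settings: GeneratorSettings | None = None,
    switch_time_us: float = MIN_SWITCH_TIME_US,
    slot_duration_us: float | None = None,
    dt_us: float = DEFAULT_DT_US,
) -> StimSchedule:
    """Place every enabled channel's pulse at the start of its STS timeslot.

    ``specs`` maps flat channel index (0..63) to the pulse spec for that
    channel. Channels with STP=0 are absent from the schedule; channels
    flagged as reference returns (RP=1) are enabled on the switch matrix but
    emit no stimulus, so they also produce no event. The slot duration
    defaults to the longest enabled pulse plus the switching time; pass
    ``slot_duration_us`` to reproduce a fixed-window recording.
    """
    if switch_time_us < MIN_SWITCH_TIME_US:
        raise ValueError(
            f"switch_time_us must be >= the minimum {MIN_SWITCH_TIME_US} μs multiplex switching time"
        )
    if settings is None:
        settings = GeneratorSettings()

    active: list[tuple[ChannelAddress, int, CurrentWaveform]] = []
    seen_slots: dict[tuple[int, int], int] = {}
    for flat in range(N_CHANNELS):
        if regfile.stp[flat] == 0:
            continue
        addr = ChannelAddress.from_flat(flat)
        slot = regfile.sts[flat]
        key = (addr.generator, slot)
        if key in seen_slots:
            other = ChannelAddress.from_flat(seen_slots[key])
            raise SlotConflictError(
                f"generator {addr.generator}: channels {other.channel} and "
                f"{addr.channel} both assigned timeslot {slot}"
            )
        seen_slots[key] = flat
        if regfile.rp[flat]:
            continue  # return electrode: connected, not stimulated
        if flat not in specs:
            raise ValueError(f"enabled channel {flat} has no pulse spec")
        active.append((addr, slot, synthesize_pulse(specs[flat], settings, dt_us)))

    max_len = max((wf.sample_times_us[-1] for _a, _s, wf in active), default=0.0)
    if slot_duration_us is None:
        slot_duration_us = max_len + switch_time_us
    elif slot_duration_us < max_len + switch_time_us:
        raise ValueError(
            f"slot_duration_us {slot_duration_us} shorter than longest pulse + switching "
            f"({max_len + switch_time_us:.1f} μs)"
        )

    events = tuple(
        StimEvent(addr, slot, slot * slot_duration_us, wf)
        for addr, slot, wf in sorted(active, key=lambda t: (t[1], t[0].generator))
    )
    return StimSchedule(events=events, slot_duration_us=float(slot_duration_us))


def max_repetition_rate(
    pulse_len_us: float,
    n_slots: int = N_SLOTS,
    switch_time_us: float = MIN_SWITCH_TIME_US,
) -> float:
    """Maximum per-channel pulse repetition rate in Hz.

    A channel fires once per window and the window is
    ``n_slots × (pulse_len + switch_time)``, so the rate is
    ``10^6 / (n_slots × (pulse_len_us + switch_time_us))`` — about 306 Hz for
    0.4 ms pulses with 8 slots and the minimum 7.8 μs switching time.
    """
    if pulse_len_us <= 0:
        raise ValueError("pulse_len_us must be positive")
    return 1e6 / (n_slots * (pulse_len_us + switch_time_us))
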
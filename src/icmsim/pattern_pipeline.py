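"""Dynamic pattern-stimulation pipeline: spike-image stream → 8×8 blocks →
chip-tagged Reg1 frames → per-chip schedules → LED-grid render.

This reproduces the desk demonstration in which a retinal circuit emulator
feeds the stimulator array: its spike output is reformatted to binary
64×64 frames at 5 ms steps; each frame is sectioned into 64 blocks of
8×8 pixels; each block, tagged with a chip ID, becomes that chip's Reg1
stimulation-position data; and an 8×8 LED array per chip (one monophasic
50 μA, 1.8 ms pulse per lit channel) visualizes the emitted pattern.

The retinal emulator itself is replaced by a minimal transient-ON stand-in:
a pixel spikes when its luminance increases by more than a contrast
threshold between consecutive frames (positive contrast steps only, no
sustained response).

Spatial mapping conventions (fixed and documented — the demonstration
hardware's actual wiring is not public): blocks tile the frame row-major,
``chip_id = 8·(row//8) + (col//8)``; within a block, pixel (r, c) maps to
generator r+1, channel c+1, i.e. STP flat index 8·r + c.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from PIL import Image

from .registers import (
    BusFrame,
    ChipRegisterFile,
    MAX_CHIPS,
    decode_frame,
    encode_frame,
)

FRAME_SIZE = 64
BLOCK_SIZE = 8
FRAME_STEP_MS = 5.0
LED_PULSE_AMP_UA = 50.0
LED_PULSE_DUR_MS = 1.8


@dataclass(frozen=True)
class SpikeFrame:
    """Binary 64×64 all-or-none spike image at one 5 ms time step."""

    grid: np.ndarray
    timestamp_ms: float = 0.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.shape != (FRAME_SIZE, FRAME_SIZE):
            raise ValueError(f"grid must be {FRAME_SIZE}×{FRAME_SIZE}, got {g.shape}")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("grid values must be 0 or 1")
        object.__setattr__(self, "grid", g.astype(np.uint8))


@dataclass(frozen=True)
class BlockAssignment:
    """One 8×8 block of a spike frame, tagged with its chip ID."""

    chip_id: int
    block: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0 <= self.chip_id < MAX_CHIPS:
            raise ValueError(f"chip_id must be 0..{MAX_CHIPS - 1}")
        b = np.asarray(self.block, dtype=np.uint8)
        if b.shape != (BLOCK_SIZE, BLOCK_SIZE):
            raise ValueError(f"block must be {BLOCK_SIZE}×{BLOCK_SIZE}")
        object.__setattr__(self, "block", b)


def downsample_to_grid(image: np.ndarray, size: int = FRAME_SIZE) -> np.ndarray:
    """Block-average a grayscale image down to size×size."""
    img = np.asarray(image, dtype=float)
    if img.shape[0] % size or img.shape[1] % size:
        raise ValueError(f"image dimensions {img.shape} must be multiples of {size}")
    br, bc = img.shape[0] // size, img.shape[1] // size
    return img.reshape(size, br, size, bc).mean(axis=(1, 3))


def transient_on_emulator(
    image_stream: Iterable[np.ndarray],
    threshold: float,
    frame_step_ms: float = FRAME_STEP_MS,
) -> Iterator[SpikeFrame]:
    """Minimal transient-ON retinal stand-in.

    A pixel spikes at frame t iff its (64×64-downsampled) intensity rose by
    more than ``threshold`` since frame t−1. The first frame never spikes;
    sustained brightness and negative contrast steps produce nothing.
    """
    prev: np.ndarray | None = None
    for k, image in enumerate(image_stream):
        cur = downsample_to_grid(image)
        if prev is None:
            grid = np.zeros((FRAME_SIZE, FRAME_SIZE), dtype=np.uint8)
        else:
            grid = (cur - prev > threshold).astype(np.uint8)
        prev = cur
        yield SpikeFrame(grid=grid, timestamp_ms=k * frame_step_ms)


def section_blocks(frame: SpikeFrame) -> list[BlockAssignment]:
    """Tile a frame into 64 chip-tagged 8×8 blocks (row-major, no overlap)."""
    out = []
    for br in range(FRAME_SIZE // BLOCK_SIZE):
        for bc in range(FRAME_SIZE // BLOCK_SIZE):
            r0, c0 = br * BLOCK_SIZE, bc * BLOCK_SIZE
            out.append(
                BlockAssignment(
                    chip_id=8 * br + bc,
                    block=frame.grid[r0:r0 + BLOCK_SIZE, c0:c0 + BLOCK_SIZE],
                    origin=(r0, c0),
                )
            )
    return out


def reassemble_blocks(blocks: Sequence[BlockAssignment], timestamp_ms: float = 0.0) -> SpikeFrame:
    """Inverse of :func:`section_blocks`."""
    grid = np.zeros((FRAME_SIZE, FRAME_SIZE), dtype=np.uint8)
    for b in blocks:
        r0, c0 = b.origin
        grid[r0:r0 + BLOCK_SIZE, c0:c0 + BLOCK_SIZE] = b.block
    return SpikeFrame(grid=grid, timestamp_ms=timestamp_ms)


def block_to_stp(block: np.ndarray) -> tuple[int, ...]:
    """Map block pixel (r, c) to the STP bit of generator r+1, channel c+1."""
    return tuple(int(v) for v in np.asarray(block, dtype=np.uint8).ravel())


def blocks_to_reg1_stream(blocks: Sequence[BlockAssignment]) -> list[BusFrame]:
    """Serialize one display frame's blocks as Reg1 bus frames in chip order."""
    frames = []
    for b in sorted(blocks, key=lambda b: b.chip_id):
        regfile = ChipRegisterFile(chip_id=b.chip_id, stp=block_to_stp(b.block))
        frames.append(encode_frame(regfile, "reg1"))
    return frames


def apply_reg1_stream(
    frames: Sequence[BusFrame], chips: Sequence[ChipRegisterFile]
) -> list[ChipRegisterFile]:
    """Broadcast Reg1 frames on the common bus to an array of chips."""
    out = list(chips)
    for frame in frames:
        out = [decode_frame(frame, chip) for chip in out]
    return out


def render_led(
    regfile: ChipRegisterFile,
    n_steps: int = 1,
    pulse_amp_uA: float = LED_PULSE_AMP_UA,
    pulse_dur_ms: float = LED_PULSE_DUR_MS,
) -> np.ndarray:
    """Render one chip's 8×8 LED array over time.

    Each enabled channel (STP=1) drives its LED with a monophasic pulse
    (default 50 μA, 1.8 ms), so the LED at (generator, channel) is lit for
    the frames whose stimulation window contains its pulse. Returns a
    (n_steps, 8, 8) binary array; with the defaults the 1.8 ms pulse fits in
    a single 5 ms display step, so each lit LED is on for one step.
    """
    if pulse_amp_uA <= 0 or pulse_dur_ms <= 0:
        raise ValueError("LED pulse amplitude and duration must be positive")
    stp = np.asarray(regfile.stp, dtype=np.uint8).reshape(BLOCK_SIZE, BLOCK_SIZE)
    on_steps = max(1, int(np.ceil(pulse_dur_ms / FRAME_STEP_MS)))
    out = np.zeros((n_steps, BLOCK_SIZE, BLOCK_SIZE), dtype=np.uint8)
    out[:min(on_steps, n_steps)] = stp
    return out


def render_led_timeline(schedule, dt_us: float = 10.0) -> np.ndarray:
    """Time-resolved LED render of a single chip's stimulation schedule.

    Returns a (T, 8, 8) binary sequence sampled at ``dt_us`` over the
    stimulation window: LED (generator, channel) is on while its scheduled
    pulse is being delivered in its timeslot.
    """
    n = int(np.ceil(schedule.window_duration_us / dt_us))
    out = np.zeros((max(n, 1), BLOCK_SIZE, BLOCK_SIZE), dtype=np.uint8)
    for e in schedule.events:
        g, ch = e.address.generator - 1, e.address.channel - 1
        k0 = int(round(e.start_us / dt_us))
        k1 = int(round((e.start_us + e.duration_us) / dt_us))
        out[k0:max(k1, k0 + 1), g, ch] = 1
    return out


def pipeline_frame(frame: SpikeFrame) -> SpikeFrame:
    """Run one spike frame end-to-end through the emulated system.

    Sections the frame into blocks, serializes them as chip-tagged Reg1 bus
    frames, broadcasts those to a fresh 64-chip array, renders every chip's
    LED grid and reassembles the union into a 64×64 image. For any input
    this round-trip is the identity — the in-silico version of the observed
    correspondence between input spikes and lit LEDs.
    """
    frames = blocks_to_reg1_stream(section_blocks(frame))
    chips = apply_reg1_stream(frames, [ChipRegisterFile(chip_id=i) for i in range(MAX_CHIPS)])
    blocks = []
    for chip in chips:
        lit = render_led(chip, n_steps=1)[0]
        origin = (BLOCK_SIZE * (chip.chip_id // 8), BLOCK_SIZE * (chip.chip_id % 8))
        blocks.append(BlockAssignment(chip_id=chip.chip_id, block=lit, origin=origin))
    return reassemble_blocks(blocks, timestamp_ms=frame.timestamp_ms)


# ---------------------------------------------------------------------------
# Frame I/O: PGM/PBM images via Pillow, plain CSV rasters via numpy.

def read_image_frame(path: str | Path) -> np.ndarray:
    """Read a grayscale image (PGM/PBM/PNG...) as a float array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("F"), dtype=float)


def spike_frame_to_csv(frame: SpikeFrame, path: str | Path) -> None:
    np.savetxt(path, frame.grid, fmt="%d", delimiter=",")


def spike_frame_from_csv(path: str | Path, timestamp_ms: float = 0.0) -> SpikeFrame:
    return SpikeFrame(np.loadtxt(path, delimiter=",", dtype=int), timestamp_ms)
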
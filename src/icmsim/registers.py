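"""Bit-exact model of the stimulation module's on-chip register memory.

A single module chip drives 64 electrodes through eight 8-channel current
generators. Its configuration lives in three register groups that differ in
update frequency:

* **Reg1** — stimulation position: one on/off bit per channel (64 bits),
  rewritten every display frame.
* **Reg2** — stimulation sequence: a 3-bit timeslot index per channel
  (192 bits), rewritten occasionally.
* **Reg3** — everything else: per-channel anodic/cathodic amplitude codes,
  reference-channel flags and pulse-width-adjustment codes, plus per-side
  (left/right generator bank) max-amplitude, inrush-suppression and bias
  settings (1160 bits), written once at start-up.

Up to 64 chips share one 10 Mbps serial bus. Every register-setting frame
starts with the 6-bit chip-ID header; a chip applies the payload only when
the header matches its pre-assigned ID. Frame lengths are fixed by the bus
arithmetic: a Reg1 update frame is 73 bits (6 header + 64 payload + 3
framing) and an initialization frame carrying Reg2 and Reg3 is 1362 bits
(6 + 1352 + 4).

Serialization order is fixed and documented: fields in register-map row
order (STP, STS, AP, CP, RP, PA, MA, ICS, OTR), entries in flat channel
order (generator-major), each value MSB-first. The signed 4-bit PA code
(−7..+8) is stored offset-binary (value + 7). The OTR payload is carried
opaquely; its semantics are not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

N_GENERATORS = 8
N_CHANNELS_PER_GENERATOR = 8
N_CHANNELS = N_GENERATORS * N_CHANNELS_PER_GENERATOR
N_SIDES = 2  # left/right generator banks share MA/ICS/OTR
CHIP_ID_BITS = 6
MAX_CHIPS = 2 ** CHIP_ID_BITS

REG1_FRAMING_BITS = 3
INIT_FRAMING_BITS = 4

# (name, count, bits_per_entry, group, signed_offset)
# signed_offset is added before packing so stored codes are non-negative.
_FIELD_LAYOUT = (
    ("stp", N_CHANNELS, 1, "reg1", 0),
    ("sts", N_CHANNELS, 3, "reg2", 0),
    ("ap", N_CHANNELS, 6, "reg3", 0),
    ("cp", N_CHANNELS, 6, "reg3", 0),
    ("rp", N_CHANNELS, 1, "reg3", 0),
    ("pa", N_CHANNELS, 4, "reg3", 7),
    ("ma", N_SIDES, 2, "reg3", 0),
    ("ics", N_SIDES, 2, "reg3", 0),
    ("otr", N_SIDES, 32, "reg3", 0),
)


@dataclass(frozen=True)
class ChannelAddress:
    """One of the 64 outputs, addressed as (generator 1..8, channel 1..8)."""

    generator: int
    channel: int

    def __post_init__(self) -> None:
        if not 1 <= self.generator <= N_GENERATORS:
            raise ValueError(f"generator must be 1..{N_GENERATORS}, got {self.generator}")
        if not 1 <= self.channel <= N_CHANNELS_PER_GENERATOR:
            raise ValueError(f"channel must be 1..{N_CHANNELS_PER_GENERATOR}, got {self.channel}")

    @property
    def flat_index(self) -> int:
        """Generator-major flat index in 0..63."""
        return (self.generator - 1) * N_CHANNELS_PER_GENERATOR + (self.channel - 1)

    @classmethod
    def from_flat(cls, index: int) -> "ChannelAddress":
        if not 0 <= index < N_CHANNELS:
            raise ValueError(f"flat index must be 0..{N_CHANNELS - 1}, got {index}")
        return cls(index // N_CHANNELS_PER_GENERATOR + 1, index % N_CHANNELS_PER_GENERATOR + 1)

    @property
    def side(self) -> int:
        """0 for the left bank (generators 1-4), 1 for the right (5-8)."""
        return 0 if self.generator <= N_GENERATORS // 2 else 1


def _check_range(name: str, values: Sequence[int], lo: int, hi: int, count: int) -> tuple[int, ...]:
    vals = tuple(int(v) for v in values)
    if len(vals) != count:
        raise ValueError(f"{name} must have {count} entries, got {len(vals)}")
    for v in vals:
        if not lo <= v <= hi:
            raise ValueError(f"{name} entries must be in {lo}..{hi}, got {v}")
    return vals


@dataclass(frozen=True)
class ChipRegisterFile:
    """Complete register contents of one chip.

    All per-channel fields are 64-tuples in flat channel order; `ma`, `ics`
    and `otr` are 2-tuples (left bank, right bank).
    """

    chip_id: int = 0
    stp: tuple[int, ...] = (0,) * N_CHANNELS
    sts: tuple[int, ...] = (0,) * N_CHANNELS
    ap: tuple[int, ...] = (0,) * N_CHANNELS
    cp: tuple[int, ...] = (0,) * N_CHANNELS
    rp: tuple[int, ...] = (0,) * N_CHANNELS
    pa: tuple[int, ...] = (0,) * N_CHANNELS
    ma: tuple[int, ...] = (0,) * N_SIDES
    ics: tuple[int, ...] = (0,) * N_SIDES
    otr: tuple[int, ...] = (0,) * N_SIDES

    def __post_init__(self) -> None:
        if not 0 <= self.chip_id < MAX_CHIPS:
            raise ValueError(f"chip_id must be 0..{MAX_CHIPS - 1}, got {self.chip_id}")
        object.__setattr__(self, "stp", _check_range("stp", self.stp, 0, 1, N_CHANNELS))
        object.__setattr__(self, "sts", _check_range("sts", self.sts, 0, 7, N_CHANNELS))
        object.__setattr__(self, "ap", _check_range("ap", self.ap, 0, 63, N_CHANNELS))
        object.__setattr__(self, "cp", _check_range("cp", self.cp, 0, 63, N_CHANNELS))
        object.__setattr__(self, "rp", _check_range("rp", self.rp, 0, 1, N_CHANNELS))
        object.__setattr__(self, "pa", _check_range("pa", self.pa, -7, 8, N_CHANNELS))
        object.__setattr__(self, "ma", _check_range("ma", self.ma, 0, 3, N_SIDES))
        object.__setattr__(self, "ics", _check_range("ics", self.ics, 0, 3, N_SIDES))
        object.__setattr__(self, "otr", _check_range("otr", self.otr, 0, 2 ** 32 - 1, N_SIDES))


def register_group_sizes() -> tuple[int, int, int]:
    """Bit sizes of the three register groups, summed from the field widths.

    Returns (Reg1, Reg2, Reg3) = (64, 192, 1160).
    """
    sizes = {"reg1": 0, "reg2": 0, "reg3": 0}
    for _name, count, width, group, _off in _FIELD_LAYOUT:
        sizes[group] += count * width
    return sizes["reg1"], sizes["reg2"], sizes["reg3"]


def _int_to_bits(value: int, width: int) -> list[int]:
    if not 0 <= value < (1 << width):
        raise ValueError(f"value {value} does not fit in {width} bits")
    return [(value >> (width - 1 - i)) & 1 for i in range(width)]


def _bits_to_int(bits: Sequence[int]) -> int:
    out = 0
    for b in bits:
        out = (out << 1) | (b & 1)
    return out


def _pack_fields(regfile: ChipRegisterFile, groups: tuple[str, ...]) -> list[int]:
    bits: list[int] = []
    for name, _count, width, group, offset in _FIELD_LAYOUT:
        if group not in groups:
            continue
        for v in getattr(regfile, name):
            bits.extend(_int_to_bits(v + offset, width))
    return bits


def _unpack_fields(bits: Sequence[int], groups: tuple[str, ...]) -> dict[str, tuple[int, ...]]:
    out: dict[str, tuple[int, ...]] = {}
    pos = 0
    for name, count, width, group, offset in _FIELD_LAYOUT:
        if group not in groups:
            continue
        vals = []
        for _ in range(count):
            vals.append(_bits_to_int(bits[pos:pos + width]) - offset)
            pos += width
        out[name] = tuple(vals)
    if pos != len(bits):
        raise ValueError(f"payload has {len(bits)} bits, expected {pos}")
    return out


_KIND_GROUPS = {"reg1": ("reg1",), "init": ("reg2", "reg3")}
_KIND_FRAMING = {"reg1": REG1_FRAMING_BITS, "init": INIT_FRAMING_BITS}


@dataclass(frozen=True)
class BusFrame:
    """One register-setting frame on the common serial bus."""

    kind: str
    chip_id: int
    payload_bits: tuple[int, ...]
    framing_bits: tuple[int, ...]

    @property
    def bits(self) -> tuple[int, ...]:
        return tuple(_int_to_bits(self.chip_id, CHIP_ID_BITS)) + self.payload_bits + self.framing_bits

    def __len__(self) -> int:
        return CHIP_ID_BITS + len(self.payload_bits) + len(self.framing_bits)


def frame_length_bits(kind: str) -> int:
    """Total serial length of a frame of the given kind (73 or 1362 bits)."""
    if kind not in _KIND_GROUPS:
        raise ValueError(f"unknown frame kind {kind!r}")
    payload = sum(
        count * width for _n, count, width, group, _o in _FIELD_LAYOUT if group in _KIND_GROUPS[kind]
    )
    return CHIP_ID_BITS + payload + _KIND_FRAMING[kind]


def encode_frame(regfile: ChipRegisterFile, kind: str) -> BusFrame:
    """Serialize one register group of a chip into a bus frame.

    ``kind`` selects the frame: ``"reg1"`` carries the 64 STP bits (73-bit
    frame), ``"init"`` carries Reg2 followed by Reg3 (1362-bit frame).
    """
    if kind not in _KIND_GROUPS:
        raise ValueError(f"unknown frame kind {kind!r}, expected 'reg1' or 'init'")
    payload = _pack_fields(regfile, _KIND_GROUPS[kind])
    framing = (0,) * _KIND_FRAMING[kind]
    frame = BusFrame(kind=kind, chip_id=regfile.chip_id, payload_bits=tuple(payload), framing_bits=framing)
    assert len(frame) == frame_length_bits(kind)
    return frame


def decode_frame(frame: BusFrame, target: ChipRegisterFile) -> ChipRegisterFile:
    """Apply a bus frame to a chip, mimicking the chip-selector circuit.

    The register group carried by the frame replaces the target's contents
    only when the frame header matches the chip's pre-assigned ID; otherwise
    the target is returned unchanged. ``decode_frame(encode_frame(x, k), x)``
    is the identity for any register content.
    """
    expected = frame_length_bits(frame.kind)
    if len(frame) != expected:
        raise ValueError(
            f"malformed {frame.kind} frame: {len(frame)} bits, expected {expected}"
        )
    if frame.chip_id != target.chip_id:
        return target
    fields = _unpack_fields(frame.payload_bits, _KIND_GROUPS[frame.kind])
    return replace(target, **fields)


# ---------------------------------------------------------------------------
# External interchange: hex bitstream files and JSON register documents.

_BITSTREAM_HEADER = "# icmsim bitstream v1"


def _bits_to_hex(bits: Sequence[int]) -> str:
    padded = list(bits) + [0] * (-len(bits) % 4)
    return "".join(f"{_bits_to_int(padded[i:i + 4]):X}" for i in range(0, len(padded), 4))


def _hex_to_bits(text: str, n_bits: int) -> tuple[int, ...]:
    bits: list[int] = []
    for ch in text.strip():
        bits.extend(_int_to_bits(int(ch, 16), 4))
    if len(bits) < n_bits or any(bits[n_bits:]):
        raise ValueError(f"hex frame does not hold exactly {n_bits} bits")
    return tuple(bits[:n_bits])


def write_bitstream(frames: Iterable[BusFrame], path: str | Path) -> None:
    """Write frames as hex text, one frame per line prefixed by its kind."""
    lines = [_BITSTREAM_HEADER]
    for fr in frames:
        lines.append(f"{fr.kind} {_bits_to_hex(fr.bits)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bitstream(path: str | Path) -> list[BusFrame]:
    """Read a hex bitstream file back into bus frames."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _BITSTREAM_HEADER:
        raise ValueError("not an icmsim bitstream file (missing header line)")
    frames = []
    for line in lines[1:]:
        if not line.strip():
            continue
        kind, hexpart = line.split(maxsplit=1)
        bits = _hex_to_bits(hexpart, frame_length_bits(kind))
        chip_id = _bits_to_int(bits[:CHIP_ID_BITS])
        n_framing = _KIND_FRAMING[kind]
        frames.append(
            BusFrame(
                kind=kind,
                chip_id=chip_id,
                payload_bits=bits[CHIP_ID_BITS:len(bits) - n_framing],
                framing_bits=bits[len(bits) - n_framing:],
            )
        )
    return frames


_JSON_KEYS = {"stp": "STP", "sts": "STS", "ap": "AP", "cp": "CP", "rp": "RP",
              "pa": "PA", "ma": "MA", "ics": "ICS", "otr": "OTR"}


def regfile_to_json(regfile: ChipRegisterFile, path: str | Path | None = None) -> dict:
    """Serialize a register file to a JSON document mirroring the register map."""
    doc = {"chip_id": regfile.chip_id}
    doc.update({key: list(getattr(regfile, attr)) for attr, key in _JSON_KEYS.items()})
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")
    return doc


def regfile_from_json(source: dict | str | Path) -> ChipRegisterFile:
    """Load a register file from a JSON document or file."""
    if not isinstance(source, dict):
        source = json.loads(Path(source).read_text())
    kwargs = {"chip_id": int(source.get("chip_id", 0))}
    for attr, key in _JSON_KEYS.items():
        if key in source:
            kwargs[attr] = tuple(int(v) for v in source[key])
    return ChipRegisterFile(**kwargs)
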
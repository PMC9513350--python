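import numpy as np
import pytest

from icmsim.registers import ChipRegisterFile, N_CHANNELS, N_SIDES


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_regfile(rng: np.random.Generator, chip_id: int | None = None) -> ChipRegisterFile:
    """Uniformly random register contents (valid field ranges)."""
    return ChipRegisterFile(
        chip_id=int(rng.integers(0, 64)) if chip_id is None else chip_id,
        stp=tuple(rng.integers(0, 2, N_CHANNELS)),
        sts=tuple(rng.integers(0, 8, N_CHANNELS)),
        ap=tuple(rng.integers(0, 64, N_CHANNELS)),
        cp=tuple(rng.integers(0, 64, N_CHANNELS)),
        rp=tuple(rng.integers(0, 2, N_CHANNELS)),
        pa=tuple(rng.integers(-7, 9, N_CHANNELS)),
        ma=tuple(rng.integers(0, 4, N_SIDES)),
        ics=tuple(rng.integers(0, 4, N_SIDES)),
        otr=tuple(int(v) for v in rng.integers(0, 2 ** 32, N_SIDES, dtype=np.uint64)),
    )
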
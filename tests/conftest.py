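import numpy as np
import pytest

from thermoseq.records import ALPHABET, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture
def make_record(rng):
    def _make(length: int = 120, rid: str = "R1", label: float | None = None):
        return ProteinRecord(id=rid, sequence=random_sequence(rng, length), label=label)

    return _make
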
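import numpy as np
import pytest

from firetrace.io import SequenceRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


@pytest.fixture
def make_record():
    def _make(seq, id="seq", clade=""):
        return SequenceRecord(id=id, seq=seq, clade=clade)

    return _make
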
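import numpy as np
import pytest

from radphylo.assembly import OrthologLocus
from radphylo.io import BarcodedRead


def make_read(read_id: str, seq: str, qual: int = 35) -> BarcodedRead:
    return BarcodedRead(read_id, seq, tuple([qual] * len(seq)))


def mutate(seq: str, positions, base_shift: int = 1) -> str:
    """Deterministically substitute bases at the given positions."""
    alphabet = "ACGT"
    chars = list(seq)
    for pos in positions:
        chars[pos] = alphabet[(alphabet.index(chars[pos]) + base_shift) % 4]
    return "".join(chars)


def random_seq(rng: np.random.Generator, length: int = 90) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_locus():
    """Four-sample locus with one informative and one singleton site."""
    base = "ACGTACGTAC"
    return OrthologLocus(
        locus_id="toy",
        rows={
            "s1": base,
            "s2": base,
            "s3": mutate(base, [0]),
            "s4": mutate(base, [0, 5]),
        },
    )
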
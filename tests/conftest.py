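import numpy as np
import pytest

from itseval.records import SeqRecord

BASES = np.array(list("ACGT"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def mutate_seq(rng, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([c for c in "ACGT" if c != ch]))
        else:
            out.append(ch)
    return "".join(out)


def make_records(seqs, prefix="r"):
    return [SeqRecord(id=f"{prefix}{i}", sequence=s)
            for i, s in enumerate(seqs)]
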
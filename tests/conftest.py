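import numpy as np
import pytest

from pepclust.msa import MSA
from pepclust.seqio import Occurrence, UniqueSequence
from pepclust.substitution import (AMINO_ACIDS, SubstitutionMatrix, blosum62,
                                   uniform_background)


@pytest.fixture(scope="session")
def b62():
    return blosum62()


@pytest.fixture(scope="session")
def identity_matrix():
    """Match 1 / mismatch 0 — convenient for hand-simulated examples."""
    return SubstitutionMatrix(name="identity", scores=np.eye(20, dtype=int))


@pytest.fixture(scope="session")
def uniform_bg():
    return uniform_background()


def make_unique(seq: str, count: int = 1, label: str | None = None) -> UniqueSequence:
    u = UniqueSequence(seq)
    u.counts[label or "_nolabel"] = count
    return u


def make_msa(*aligned: str) -> MSA:
    """Rows named by their degapped sequence."""
    return MSA([(a.replace("-", ""), a) for a in aligned])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
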
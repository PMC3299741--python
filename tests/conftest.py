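import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from structmsa import AnnotatedSequence, SubstitutionMatrix, default_weights

REDUCED = "ACDE"


@pytest.fixture(scope="session")
def gonnet():
    return SubstitutionMatrix.gonnet()


@pytest.fixture
def cfg():
    return default_weights()


def random_seq(rng, max_len=4, alphabet=REDUCED, name="s", with_ann=False):
    n = int(rng.integers(1, max_len + 1))
    residues = "".join(alphabet[k] for k in rng.integers(0, len(alphabet), n))
    ss = sa = None
    if with_ann:
        ss = "".join("HEC"[k] for k in rng.integers(0, 3, n))
        sa = "".join("eb"[k] for k in rng.integers(0, 2, n))
    return AnnotatedSequence(id=name, residues=residues, ss=ss, sa=sa)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
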
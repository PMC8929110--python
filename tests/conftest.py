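import numpy as np
import pytest

from utr_mirscan import MiRNA, UTRSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20210706)


@pytest.fixture
def let7():
    return MiRNA("hsa-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def utr_4k(rng):
    seq = "".join(rng.choice(list("ACGU"), size=4000))
    return UTRSequence("utr-4k", seq)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
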
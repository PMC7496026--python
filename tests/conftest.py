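import numpy as np
import pytest

from promdiv.align import PairwiseAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def mk_aln(row_a: str, row_b: str, **kw) -> PairwiseAlignment:
    return PairwiseAlignment(row_a, row_b, **kw)


def random_seq(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))
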
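import numpy as np
import pytest

from domainsel.alignments import CodonAlignment


@pytest.fixture
def toy_alignment() -> CodonAlignment:
    """Four 6-bp sequences with S=2, eta=2, k_hat=7/6, 3 haplotypes."""
    return CodonAlignment(
        (
            ("s1", "ATGAAA"),
            ("s2", "ATGAAA"),
            ("s3", "ATGAAT"),
            ("s4", "ATGTAT"),
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
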
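import numpy as np
import pytest

from kcapture import (
    SequenceRecord,
    distance_to_similarity,
    grantham_matrix,
)
from kcapture.physchem import CANONICAL_RESIDUES


@pytest.fixture(scope="session")
def grantham():
    return grantham_matrix()


@pytest.fixture(scope="session")
def sim(grantham):
    return distance_to_similarity(grantham)


def random_records(rng, n, min_len=10, max_len=30, prefix="s"):
    """Uniform-random canonical sequences with deterministic ids."""
    records = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(
            CANONICAL_RESIDUES[j] for j in rng.integers(0, 20, length)
        )
        records.append(SequenceRecord(f"{prefix}{i + 1:02d}", seq))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
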
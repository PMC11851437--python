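import numpy as np
import pandas as pd
import pytest

from fibi import OccurrenceMatrix, TraitMatrix


@pytest.fixture
def tiny_vocab():
    return {"A": "trait a", "B": "trait b", "NOT_A": "complement of a"}


@pytest.fixture
def small_occurrence():
    """4 sites x 6 species with hand-checkable structure."""
    data = pd.DataFrame(
        [
            [1, 1, 1, 0, 0, 0],
            [1, 1, 0, 1, 0, 0],
            [0, 0, 1, 1, 1, 0],
            [0, 0, 0, 1, 1, 1],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"sp{i}" for i in range(1, 7)],
    )
    return OccurrenceMatrix(data, era="historical")


@pytest.fixture
def small_traits(tiny_vocab):
    """Traits for the 6 species; NOT_A is the complement of A."""
    a = [1, 0, 1, 0, 1, 0]
    b = [1, 1, 0, 0, 1, 1]
    data = pd.DataFrame(
        {"A": a, "B": b, "NOT_A": [1 - v for v in a]},
        index=[f"sp{i}" for i in range(1, 7)],
    )
    return TraitMatrix(data, vocabulary=tiny_vocab)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
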
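import numpy as np
import pytest

from scmultinom import CountMatrix


def random_counts(seed: int, I: int = 20, J: int = 30,
                  mean: float = 2.0) -> CountMatrix:
    """Poisson count matrix with no all-zero cells (retry the rare ones)."""
    rng = np.random.default_rng(seed)
    y = rng.poisson(mean, size=(I, J))
    empty = y.sum(axis=1) == 0
    while empty.any():
        y[empty] = rng.poisson(mean, size=(int(empty.sum()), J))
        empty = y.sum(axis=1) == 0
    return CountMatrix(y)


@pytest.fixture
def small_counts() -> CountMatrix:
    return CountMatrix([[1, 2, 3, 4], [4, 3, 2, 1], [2, 2, 2, 2]],
                       cell_ids=["a", "b", "c"])


@pytest.fixture
def rand_counts() -> CountMatrix:
    return random_counts(0, I=40, J=60)
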
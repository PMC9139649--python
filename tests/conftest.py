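import numpy as np
import pytest

from frlf import ScoreMatrix


def random_normalized_matrix(rng: np.random.Generator, n: int, c: int) -> ScoreMatrix:
    """Random strictly positive rows summing to one (Dirichlet draws)."""
    return ScoreMatrix(rng.dirichlet(np.ones(c), size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def worked_example() -> ScoreMatrix:
    """Two binary models: (0.9, 0.1) and (0.6, 0.4)."""
    return ScoreMatrix(np.array([[0.9, 0.1], [0.6, 0.4]]), ["M1", "M2"], ["pd", "non_pd"])
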
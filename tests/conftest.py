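import numpy as np
import pytest

from gwalign import DissimilarityMatrix


@pytest.fixture
def random_dissimilarity():
    """Factory for random symmetric zero-diagonal matrices."""

    def make(n: int, seed: int = 0, scale: float = 1.0) -> DissimilarityMatrix:
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.1, scale, size=(n, n))
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        labels = [f"c{i}" for i in range(n)]
        return DissimilarityMatrix(tuple(labels), values)

    return make
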
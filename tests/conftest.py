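import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


def random_pd(rng: np.random.Generator, p: int, n_factor: int = 2) -> np.ndarray:
    """A well-conditioned random positive definite matrix (Wishart-style)."""
    A = rng.standard_normal((p, n_factor * p))
    return A @ A.T / (n_factor * p)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
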
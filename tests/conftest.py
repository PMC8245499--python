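import numpy as np
import pytest

from acpstep import CANONICAL_AA, SynthConfig, generate

# small grids keep SVM tests fast; grid-search behaviour itself is exercised
# separately on toy data
FAST_C_GRID = (1.0, 8.0, 64.0)
FAST_GAMMA_GRID = (2.0**-7, 2.0**-4, 2.0**-1)


def random_peptides(n, rng, min_len=11, max_len=40):
    alphabet = np.array(list(CANONICAL_AA))
    return [
        "".join(rng.choice(alphabet, size=rng.integers(min_len, max_len + 1)))
        for _ in range(n)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def random_sequences(rng):
    return random_peptides(100, rng)


@pytest.fixture(scope="session")
def small_synthetic():
    """120 positives / 240 negatives with strong planted structure."""
    return generate(SynthConfig(n_pos=120, n_neg=240, seed=42))
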
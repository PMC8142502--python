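import numpy as np
import pytest

from mooncop import synthdata
from mooncop.seqio import ALPHABET


@pytest.fixture(scope="session")
def fixtures_ds():
    return synthdata.worked_fixtures()


@pytest.fixture(scope="session")
def random_sequences():
    """100 random sequences of length 31-80 for oracle cross-checks."""
    rng = np.random.default_rng(20240901)
    out = []
    for _ in range(100):
        n = int(rng.integers(31, 81))
        out.append("".join(ALPHABET[i] for i in rng.integers(0, 20, size=n)))
    return out


@pytest.fixture(scope="session")
def small_dataset():
    """A small separable synthetic dataset shared across CV tests."""
    ds, _ = synthdata.generate(synthdata.SynthConfig(
        n_per_class=25, delta=0.8, seed=11))
    return ds
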
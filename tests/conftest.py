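import numpy as np
import pytest

from splicecode import Vocabulary, default_spec, generate_dataset

CONDITIONS = ("liverlike", "cerebellumlike")


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary(k=6, conditions=CONDITIONS)


@pytest.fixture(scope="session")
def small_dataset():
    """A small grammar dataset shared by unit tests (fast to generate)."""
    return generate_dataset(default_spec(CONDITIONS), 80, CONDITIONS, seed=11)


@pytest.fixture(scope="session")
def grammar_spec():
    return default_spec(CONDITIONS)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
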
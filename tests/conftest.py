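import numpy as np
import pytest

from magcentric import io, simulate


@pytest.fixture(scope="session")
def crossover_metadata():
    return simulate.crossover_metadata()


@pytest.fixture(scope="session")
def filtered_metadata(crossover_metadata):
    return io.filter_samples(crossover_metadata)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
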
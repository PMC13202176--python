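import numpy as np
import pytest

from chromodyn import (
    FiberSpec,
    NucleosomeRecord,
    build_fiber,
    build_topology,
)


@pytest.fixture(scope="session")
def dinucleosome():
    """Two canonical nucleosomes joined by a 63-bp linker."""
    spec = FiberSpec(
        "dinucleosome", 2 * 147 + 63,
        [NucleosomeRecord(73.5), NucleosomeRecord(73.5 + 147 + 63)],
        [0, 63, 0])
    return build_fiber(spec)


@pytest.fixture(scope="session")
def dinucleosome_topology(dinucleosome):
    return build_topology(dinucleosome)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
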
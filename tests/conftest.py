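import numpy as np
import pytest

from swingerscan import ReferenceDB
from swingerscan.synthetic import SimulationConfig, generate_reference, plant_reads


@pytest.fixture(scope="session")
def small_reference():
    """One seeded 10 kb random reference (human-like GC)."""
    cfg = SimulationConfig(reference_length=10_000, gc=0.41, seed=11)
    return generate_reference(cfg)


@pytest.fixture(scope="session")
def small_db(small_reference):
    return ReferenceDB(small_reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_dna(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
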
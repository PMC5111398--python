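import numpy as np
import pytest

from mitopool import simulate as sim
from mitopool.mapper import build_index


@pytest.fixture(scope="session")
def small_library():
    """Six short circular references (~2 kb) with unique 100-bp windows."""
    lib, meta = sim.simulate_reference_library(
        n_species=6, length_range=(9_000, 10_000), seed=11
    )
    # shorten to keep brute-force oracles cheap while preserving uniqueness
    short = sim.ReferenceLibrary(
        sim.MitoReference(r.species_id, r.sequence[:2_000], 2_000) for r in lib
    )
    sim._pairwise_repair([r.sequence for r in short], 100, 2,
                         np.random.default_rng(5), max_sweeps=20)
    return short, meta


@pytest.fixture(scope="session")
def small_index(small_library):
    lib, _ = small_library
    return build_index(lib, read_length=100)


@pytest.fixture(scope="session")
def small_truths(small_library):
    lib, meta = small_library
    return sim.simulate_truth(lib, meta, n_samples=3, seed=7)
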
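import numpy as np
import pytest
from hypothesis import settings

from straindiff.simulate import AncestorSpec, EventSpec, evolve_pair, \
    generate_ancestor

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ancestor():
    """A 60 kbp ancestor, shared across tests that only read it."""
    return generate_ancestor(AncestorSpec(genome_length=60_000, gene_count=50,
                                          rng_seed=101))


@pytest.fixture(scope="session")
def evolved_pair(small_ancestor):
    """Derived pair at 12% divergence with the default event mix."""
    events = EventSpec(substitution_rate=0.12, n_insertions=2, n_deletions=1,
                       n_divergent=1, n_translocations=1,
                       island_length_range=(2500, 5000),
                       translocation_length=6000, translocation_offset=15000,
                       rng_seed=202)
    return evolve_pair(small_ancestor, events)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
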
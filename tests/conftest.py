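import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oligofish.genome import Genome
from oligofish.simulate import ToyGenomeSpec, make_toy_genome

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_genome(seed: int, lengths, **kw) -> Genome:
    spec = ToyGenomeSpec(
        n_chromosomes=len(lengths), lengths=list(lengths), seed=seed, **kw
    )
    return make_toy_genome(spec)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_genome():
    """One 2-kb random record."""
    return random_genome(42, [2000])
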
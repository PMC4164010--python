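import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from archori.synthetic import ToyGenomeSpec, make_toy_genome  # noqa: E402


#: small, fast toy-genome conditions used by unit tests; the acceptance
#: suite uses the full-size defaults
SMALL = dict(length=20_000, origin_position=6_000, n_genes=20)


@pytest.fixture(scope="session")
def small_truth():
    return make_toy_genome(ToyGenomeSpec(seed=7, **SMALL))


@pytest.fixture(scope="session")
def small_genome(small_truth):
    return small_truth.genome


@pytest.fixture
def rng():
    return np.random.default_rng(20140915)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
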
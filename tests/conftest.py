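import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mesasim as m

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """1 Mb single-chromosome genome with one locus — cheap shared fixture."""
    genome, loci = m.build_genome(
        chrom_sizes={"16": 1_000_000}, n_loci=1, window_sizes=(50_000, 100_000),
        seed=7,
    )
    return genome, loci


@pytest.fixture(scope="session")
def desk_genome():
    """Default two-chromosome, five-locus genome."""
    genome, loci = m.build_genome(seed=11)
    return genome, loci


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
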